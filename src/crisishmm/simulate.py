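"""Synthetic experience-sampling (ESM) panel generator.

Emulates the study design that motivates this package: patients answer a short
symptom questionnaire three times a day on a 1-100 scale, yielding one
multivariate occasion per beep, with whole occasions missing when a beep goes
unanswered. The generative model is a two-level Gaussian-emission hidden
Markov model: group-level state-by-channel means with between-patient random
effects, patient-specific transition matrices obtained by perturbing the
group transition logits, and within-state Gaussian noise.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .hmm import SubjectParams, logits_from_row_probs, row_probs_from_logits, stationary_distribution

DEFAULT_CHANNELS = (
    "self_control",
    "negative_affect",
    "contact_avoidance",
    "contact_desire",
    "suicidal_ideation",
)

# Sample-level state-by-channel emission means of the four crisis states,
# ordered from lowest to highest severity (columns follow DEFAULT_CHANNELS).
STUDY_STATE_MEANS = np.array(
    [
        [43.53, 31.80, 17.29, 41.38, 3.85],
        [37.16, 49.84, 28.23, 41.59, 46.51],
        [30.25, 62.15, 40.75, 40.22, 58.07],
        [13.30, 72.31, 48.17, 6.67, 65.71],
    ]
)

# Sample-level transition matrix: the diagonal staying probabilities are the
# reported values (0.84, 0.73, 0.63, 0.57); off-diagonal mass follows the
# reported qualitative switching pattern (1 mostly to 2; 2 mostly upward;
# 3 mostly back to 2; 4 mostly to 3).
STUDY_TRANSITION = np.array(
    [
        [0.84, 0.10, 0.04, 0.02],
        [0.06, 0.73, 0.14, 0.07],
        [0.04, 0.20, 0.63, 0.13],
        [0.02, 0.13, 0.28, 0.57],
    ]
)

STUDY_MISSING_RATE = 14.23 / 60.0

_SCALE_MIN, _SCALE_MAX = 1.0, 100.0
_BEEPS_PER_DAY = 3


class ConfigError(ValueError):
    """A simulation configuration violates one of its invariants."""


@dataclass
class SimConfig:
    """Configuration of the synthetic ESM generator.

    All score-scale quantities are on the study's 1-100 item scale;
    `transition_re_sd` is on the multinomial-logit scale.
    """

    n_patients: int = 26
    n_occasions: int = 60
    n_states: int = 4
    n_channels: int = 5
    channel_names: tuple[str, ...] = DEFAULT_CHANNELS
    group_means: np.ndarray = field(default_factory=lambda: STUDY_STATE_MEANS.copy())
    between_sd: np.ndarray = field(default_factory=lambda: np.full((4, 5), 8.0))
    within_sd: np.ndarray = field(default_factory=lambda: np.full((4, 5), 12.0))
    group_transition: np.ndarray = field(default_factory=lambda: STUDY_TRANSITION.copy())
    transition_re_sd: float = 0.7
    missing_rate: float = STUDY_MISSING_RATE
    init_distribution: np.ndarray | None = None
    seed: int = 0
    clip_to_scale: bool = True

    def __post_init__(self):
        self.group_means = np.asarray(self.group_means, dtype=float)
        self.between_sd = np.asarray(self.between_sd, dtype=float)
        self.within_sd = np.asarray(self.within_sd, dtype=float)
        self.group_transition = np.asarray(self.group_transition, dtype=float)
        self.channel_names = tuple(self.channel_names)
        if self.init_distribution is None:
            self.init_distribution = stationary_distribution(self.group_transition)
        else:
            self.init_distribution = np.asarray(self.init_distribution, dtype=float)
        self.validate()

    def validate(self) -> None:
        m, K = self.n_states, self.n_channels
        if m < 1:
            raise ConfigError("n_states must be >= 1")
        if K < 1:
            raise ConfigError("n_channels must be >= 1")
        if self.n_patients < 1 or self.n_occasions < 1:
            raise ConfigError("n_patients and n_occasions must be >= 1")
        if len(self.channel_names) != K:
            raise ConfigError("channel_names length must equal n_channels")
        for name, arr in (
            ("group_means", self.group_means),
            ("between_sd", self.between_sd),
            ("within_sd", self.within_sd),
        ):
            if arr.shape != (m, K):
                raise ConfigError(f"{name} must have shape (n_states, n_channels)")
        if np.any(self.within_sd <= 0):
            raise ConfigError("within_sd must be strictly positive")
        if np.any(self.between_sd < 0):
            raise ConfigError("between_sd must be non-negative")
        if self.group_transition.shape != (m, m):
            raise ConfigError("group_transition must be square (n_states, n_states)")
        if not np.allclose(self.group_transition.sum(axis=1), 1.0, atol=1e-12):
            raise ConfigError("rows of group_transition must sum to 1")
        if np.any(self.group_transition < 0):
            raise ConfigError("group_transition entries must be non-negative")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ConfigError("missing_rate must lie in [0, 1)")
        if self.transition_re_sd < 0:
            raise ConfigError("transition_re_sd must be non-negative")
        if abs(self.init_distribution.sum() - 1.0) > 1e-12 or np.any(self.init_distribution < 0):
            raise ConfigError("init_distribution must be a probability vector")

    # -- serialization ----------------------------------------------------
    def to_yaml(self, path=None) -> str | None:
        d = asdict(self)
        for key in ("group_means", "between_sd", "within_sd", "group_transition", "init_distribution"):
            d[key] = np.asarray(d[key]).tolist()
        d["channel_names"] = list(d["channel_names"])
        text = yaml.safe_dump(d, sort_keys=False)
        if path is None:
            return text
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(text)
        return None

    @classmethod
    def from_yaml(cls, source) -> "SimConfig":
        if hasattr(source, "read"):
            data = yaml.safe_load(source)
        else:
            try:
                with open(source, "r", encoding="utf-8") as fh:
                    data = yaml.safe_load(fh)
            except (OSError, ValueError):
                data = yaml.safe_load(io.StringIO(str(source)))
        return cls(**data)


def default_study_config(recovery: bool = False, seed: int = 0) -> SimConfig:
    """The study-design configuration: 26 patients x 60 occasions, 4 states,
    5 channels, state means and staying probabilities at the reported
    sample-level values, missingness at the observed mean rate.

    With ``recovery=True`` the generator produces unbounded Gaussian scores
    (no clipping to [1, 100]), matching the emission model assumed by the
    estimator, for parameter-recovery experiments.
    """
    return SimConfig(seed=seed, clip_to_scale=not recovery)


@dataclass
class EsmPanel:
    """Long-format multivariate ESM panel.

    Internally one row per patient x occasion with one column per channel;
    missing observations are NaN. Occasions are 1-based and consecutive
    within patient; day/beep labels derive from a 3-beep daily design.
    """

    df: pd.DataFrame
    channels: tuple[str, ...]

    def __post_init__(self):
        self.channels = tuple(self.channels)
        required = ["patient_id", "occasion", "day", "beep", *self.channels]
        missing = [c for c in required if c not in self.df.columns]
        if missing:
            raise ValueError(f"panel missing columns: {missing}")
        self.df = self.df.loc[:, required].reset_index(drop=True)
        for pid, grp in self.df.groupby("patient_id", sort=False):
            occ = grp["occasion"].to_numpy()
            if occ[0] != 1 or np.any(np.diff(occ) != 1):
                raise ValueError(f"occasions of patient {pid!r} are not consecutive from 1")

    # -- basic accessors --------------------------------------------------
    @property
    def patient_ids(self) -> list:
        return list(dict.fromkeys(self.df["patient_id"]))

    @property
    def n_patients(self) -> int:
        return len(self.patient_ids)

    @property
    def K(self) -> int:
        return len(self.channels)

    def to_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """(y, lengths): y is (n, T_max, K) float with NaN for missing."""
        ids = self.patient_ids
        lengths = np.array(
            [int((self.df["patient_id"] == pid).sum()) for pid in ids], dtype=np.int64
        )
        y = np.full((len(ids), lengths.max(), self.K), np.nan)
        for i, pid in enumerate(ids):
            grp = self.df[self.df["patient_id"] == pid]
            y[i, : lengths[i]] = grp[list(self.channels)].to_numpy(dtype=float)
        return y, lengths

    def patient_values(self, pid) -> np.ndarray:
        grp = self.df[self.df["patient_id"] == pid]
        return grp[list(self.channels)].to_numpy(dtype=float)

    def missing_occasions_per_patient(self) -> pd.Series:
        obs = self.df[list(self.channels)].isna().all(axis=1)
        return obs.groupby(self.df["patient_id"], sort=False).sum()

    def content_hash(self) -> str:
        import hashlib

        h = hashlib.sha256()
        h.update(",".join(map(str, self.patient_ids)).encode())
        y, _ = self.to_arrays()
        h.update(np.ascontiguousarray(y).tobytes())
        return h.hexdigest()[:16]

    # -- construction / IO -------------------------------------------------
    @classmethod
    def from_values(cls, y_by_patient, patient_ids=None, channels=DEFAULT_CHANNELS) -> "EsmPanel":
        """Build a panel from per-patient (T, K) arrays (NaN = missing)."""
        rows = []
        if patient_ids is None:
            patient_ids = [f"p{i + 1:02d}" for i in range(len(y_by_patient))]
        for pid, y in zip(patient_ids, y_by_patient):
            y = np.atleast_2d(np.asarray(y, dtype=float))
            T = y.shape[0]
            occ = np.arange(1, T + 1)
            block = pd.DataFrame(
                {
                    "patient_id": pid,
                    "occasion": occ,
                    "day": (occ - 1) // _BEEPS_PER_DAY + 1,
                    "beep": (occ - 1) % _BEEPS_PER_DAY + 1,
                }
            )
            for k, name in enumerate(channels):
                block[name] = y[:, k]
            rows.append(block)
        return cls(df=pd.concat(rows, ignore_index=True), channels=tuple(channels))

    def write_csv(self, path) -> None:
        self.df.to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def read_csv(cls, path, channels=None) -> "EsmPanel":
        df = pd.read_csv(path)
        if channels is None:
            channels = tuple(c for c in df.columns if c not in ("patient_id", "occasion", "day", "beep"))
        return cls(df=df, channels=tuple(channels))


def _patient_rng(seed: int, index: int, stream: int = 0) -> np.random.Generator:
    """Per-patient stream derived only from (seed, patient index), so panels
    are reproducible under patient subsetting."""
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence((seed, stream, index))))


def draw_subject_params(config: SimConfig, rng: np.random.Generator) -> SubjectParams:
    """Subject parameters from the group-level distributions: Gaussian random
    effects on emission means and on transition row logits."""
    means = rng.normal(config.group_means, config.between_sd)
    logits = np.stack(
        [logits_from_row_probs(row) for row in config.group_transition]
    ) if config.n_states > 1 else np.zeros((1, 0))
    logits = logits + rng.normal(0.0, config.transition_re_sd, size=logits.shape)
    gamma = np.stack([row_probs_from_logits(row) for row in logits])
    return SubjectParams(means=means, sds=config.within_sd.copy(), gamma=gamma)


def simulate_panel(config: SimConfig) -> tuple[EsmPanel, pd.DataFrame, list[SubjectParams]]:
    """Simulate a panel from the two-level generative model.

    Returns (panel, true_states, subject_params); true states are defined at
    every occasion, including occasions later masked as missing. Deterministic
    given ``config.seed``.
    """
    config.validate()
    m, K, T = config.n_states, config.n_channels, config.n_occasions
    values, states_rows, subjects = [], [], []
    patient_ids = [f"p{i + 1:02d}" for i in range(config.n_patients)]
    for i, pid in enumerate(patient_ids):
        rng = _patient_rng(config.seed, i)
        subj = draw_subject_params(config, rng)
        subjects.append(subj)
        s = np.empty(T, dtype=int)
        s[0] = rng.choice(m, p=config.init_distribution)
        for t in range(1, T):
            s[t] = rng.choice(m, p=subj.gamma[s[t - 1]])
        y = rng.normal(subj.means[s], config.within_sd[s])
        if config.clip_to_scale:
            y = np.clip(y, _SCALE_MIN, _SCALE_MAX)
        values.append(y)
        states_rows.append(
            pd.DataFrame({"patient_id": pid, "occasion": np.arange(1, T + 1), "state": s + 1})
        )
    panel = EsmPanel.from_values(values, patient_ids, config.channel_names)
    if config.missing_rate > 0:
        panel = apply_missingness(panel, config.missing_rate, seed=config.seed)
    return panel, pd.concat(states_rows, ignore_index=True), subjects


def apply_missingness(panel: EsmPanel, missing_rate: float, seed: int) -> EsmPanel:
    """Mask whole occasions missing completely at random at `missing_rate`.

    Rows are retained with all channels set to NaN, never deleted; each
    patient uses its own (seed, index)-derived stream.
    """
    if not (0.0 <= missing_rate < 1.0):
        raise ConfigError("missing_rate must lie in [0, 1)")
    df = panel.df.copy()
    for i, pid in enumerate(panel.patient_ids):
        rng = _patient_rng(seed, i, stream=1)
        sel = df["patient_id"] == pid
        drop = rng.random(int(sel.sum())) < missing_rate
        idx = df.index[sel][drop]
        df.loc[idx, list(panel.channels)] = np.nan
    return EsmPanel(df=df, channels=panel.channels)


def subject_params_frame(subjects: list[SubjectParams], patient_ids, channels) -> pd.DataFrame:
    """Tidy per-patient truth table (emission means and transition rows)."""
    rows = []
    for pid, subj in zip(patient_ids, subjects):
        for s in range(subj.m):
            for k, ch in enumerate(channels):
                rows.append((pid, "mean", s + 1, ch, subj.means[s, k]))
            for j in range(subj.m):
                rows.append((pid, "transition", s + 1, f"to_{j + 1}", subj.gamma[s, j]))
    return pd.DataFrame(rows, columns=["patient_id", "parameter", "state", "column", "value"])
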