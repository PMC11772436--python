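"""Substantive outputs: state composition, state dynamics, trajectories.

These tables back the study-style figures: state-by-channel composition at
sample and patient level, staying probabilities with the >= 0.70 "high"
classification, normalized switching probabilities (off-diagonal transition
mass renormalized after discounting the diagonal), state incidence, and the
decoded per-patient crisis-state trajectories.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hmm import SubjectParams, viterbi_decode, stationary_distribution
from .fit import PosteriorSummary
from .simulate import EsmPanel

HIGH_STAYING_THRESHOLD = 0.70


def decode_panel(panel: EsmPanel, summary: PosteriorSummary) -> pd.DataFrame:
    """Viterbi decoding of every patient at subject-level posterior medians.

    Emission SDs are the group-level medians (shared across patients, as in
    the fitted model). Returns a long table (patient_id, occasion, state).
    """
    _, sigma, _ = summary.group_point_params()
    rows = []
    for pid in panel.patient_ids:
        mu_i, gamma_i = summary.subject_point_params(pid)
        params = SubjectParams(means=mu_i, sds=sigma, gamma=gamma_i)
        traj = viterbi_decode(panel.patient_values(pid), params)
        occ = np.arange(1, len(traj.states) + 1)
        rows.append(pd.DataFrame({"patient_id": pid, "occasion": occ, "state": traj.states}))
    return pd.concat(rows, ignore_index=True)


def state_composition(summary: PosteriorSummary, ordering_channel: str = "negative_affect") -> pd.DataFrame:
    """State-by-channel posterior means, sample level first then per patient.

    Long table (level, patient_id, state, channel, median, lo, hi). Requires
    a relabeled (severity-ordered) summary; monotonicity of the ordering
    channel's sample-level means is checked and reported in df.attrs.
    """
    if not summary.relabeled:
        raise ValueError("state_composition requires relabeled draws (run relabel_states first)")
    ge = summary.group_emissions
    sample = ge[ge.parameter == "mean"][["state", "channel", "median", "lo", "hi"]].copy()
    sample.insert(0, "patient_id", "")
    sample.insert(0, "level", "sample")
    patient = summary.subject_emissions.copy()
    patient.insert(0, "level", "patient")
    patient = patient[["level", "patient_id", "state", "channel", "median", "lo", "hi"]]
    out = pd.concat([sample, patient], ignore_index=True)
    if ordering_channel in summary.channels:
        ordered = sample[sample.channel == ordering_channel].sort_values("state")["median"].to_numpy()
        out.attrs["ordering_monotone"] = bool(np.all(np.diff(ordered) > 0))
        out.attrs["ordering_channel"] = ordering_channel
    return out


@dataclass
class DynamicsSummary:
    """Staying probabilities, the 'high' classification, normalized switching
    probabilities, and state incidence for one transition matrix."""

    level: str
    staying: np.ndarray
    high_flags: np.ndarray
    switching_norm: np.ndarray
    incidence: np.ndarray
    threshold: float
    unvisited: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        m = len(self.staying)
        rows = []
        for r in range(m):
            for j in range(m):
                rows.append((self.level, r + 1, j + 1,
                             self.staying[r] if r == j else np.nan,
                             bool(self.high_flags[r]) if r == j else None,
                             0.0 if r == j else self.switching_norm[r, j],
                             self.incidence[r] if r == j else np.nan))
        return pd.DataFrame(rows, columns=["level", "from_state", "to_state", "staying",
                                           "high", "switching_norm", "incidence"])


def dynamics_summary(gamma: np.ndarray, decoded: np.ndarray | None = None,
                     threshold: float = HIGH_STAYING_THRESHOLD,
                     level: str = "sample") -> DynamicsSummary:
    """Dynamics summary of a transition matrix.

    staying = the diagonal; high_flags = staying >= threshold; each row of
    switching_norm holds the off-diagonal entries divided by (1 - staying)
    (all-zero when staying = 1 within 1e-12). Incidence comes from decoded
    state occupancy when `decoded` (1-based states) is given, else from the
    stationary distribution. States absent from `decoded` are flagged as
    unvisited.
    """
    gamma = np.asarray(gamma, dtype=float)
    m = gamma.shape[0]
    if gamma.shape != (m, m) or np.any(gamma < 0) or not np.allclose(gamma.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("gamma must be a row-stochastic square matrix")
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must lie in (0, 1)")
    staying = np.diag(gamma).copy()
    high = staying >= threshold
    switching = np.zeros((m, m))
    for r in range(m):
        rest = 1.0 - staying[r]
        if rest > 1e-12:
            switching[r] = gamma[r] / rest
            switching[r, r] = 0.0
    unvisited = []
    if decoded is not None:
        decoded = np.asarray(decoded, dtype=int)
        counts = np.bincount(decoded - 1, minlength=m).astype(float)
        unvisited = [int(s + 1) for s in range(m) if counts[s] == 0]
        incidence = counts / counts.sum()
    else:
        incidence = stationary_distribution(gamma)
    return DynamicsSummary(level=level, staying=staying, high_flags=high,
                           switching_norm=switching, incidence=incidence,
                           threshold=threshold, unvisited=unvisited)


def patient_dynamics(summary: PosteriorSummary, decoded: pd.DataFrame,
                     threshold: float = HIGH_STAYING_THRESHOLD) -> list[DynamicsSummary]:
    """Per-patient dynamics summaries from subject-level posterior medians
    and decoded occupancy."""
    out = []
    for pid in summary.patient_ids:
        _, gamma_i = summary.subject_point_params(pid)
        dec = decoded[decoded.patient_id == pid]["state"].to_numpy()
        out.append(dynamics_summary(gamma_i, decoded=dec, threshold=threshold,
                                    level=f"patient:{pid}"))
    return out


def occupancy_and_trajectories(decoded: pd.DataFrame, m: int | None = None):
    """Occupancy proportions (per patient and pooled), the long trajectory
    table, and per-patient switch counts."""
    decoded = decoded.sort_values(["patient_id", "occasion"], kind="stable").reset_index(drop=True)
    if m is None:
        m = int(decoded["state"].max())
    occ_rows, switch_rows = [], []
    for pid, grp in decoded.groupby("patient_id", sort=False):
        states = grp["state"].to_numpy()
        counts = np.bincount(states - 1, minlength=m)
        props = counts / counts.sum()
        for s in range(m):
            occ_rows.append((pid, s + 1, props[s]))
        switch_rows.append((pid, int((states[1:] != states[:-1]).sum())))
    pooled = np.bincount(decoded["state"].to_numpy() - 1, minlength=m)
    pooled = pooled / pooled.sum()
    for s in range(m):
        occ_rows.append(("pooled", s + 1, pooled[s]))
    occupancy = pd.DataFrame(occ_rows, columns=["patient_id", "state", "proportion"])
    switches = pd.DataFrame(switch_rows, columns=["patient_id", "n_switches"])
    trajectories = decoded[["patient_id", "occasion", "state"]].copy()
    return occupancy, trajectories, switches


def export_report(directory, summary: PosteriorSummary, decoded: pd.DataFrame,
                  threshold: float = HIGH_STAYING_THRESHOLD) -> dict:
    """Write all report tables as tidy CSV plus one JSON bundle; returns the
    bundle as a dict."""
    import pathlib

    d = pathlib.Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    comp = state_composition(summary)
    comp.to_csv(d / "state_composition.csv", index=False)
    mu, sigma, gamma = summary.group_point_params()
    sample_dyn = dynamics_summary(gamma, decoded=decoded["state"].to_numpy(), threshold=threshold)
    frames = [sample_dyn.to_frame()] + [p.to_frame() for p in patient_dynamics(summary, decoded, threshold)]
    dyn = pd.concat(frames, ignore_index=True)
    dyn.to_csv(d / "dynamics.csv", index=False)
    occupancy, trajectories, switches = occupancy_and_trajectories(decoded, m=summary.m)
    occupancy.to_csv(d / "occupancy.csv", index=False)
    trajectories.to_csv(d / "trajectories.csv", index=False)
    switches.to_csv(d / "switch_counts.csv", index=False)
    bundle = {
        "threshold": threshold,
        "sample_staying": sample_dyn.staying.tolist(),
        "sample_high_flags": sample_dyn.high_flags.tolist(),
        "sample_incidence": sample_dyn.incidence.tolist(),
        "ordering_monotone": comp.attrs.get("ordering_monotone"),
        "n_patients": len(summary.patient_ids),
    }
    with open(d / "report_bundle.json", "w", encoding="utf-8") as fh:
        json.dump(bundle, fh, indent=2)
    return bundle
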