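"""Relative sodium signal predictions per sequence and tissue state.

Combines the compartment sodium contributions (mmol/L-tissue) with the
per-sequence relaxation weighting of each sodium environment to predict
the relative signal of control white matter, NAWM and lesions for the
three sequences.  Entries are normalized to the healthy-control
intracellular signal of the same sequence, matching the published
presentation, and percent differences are taken on the per-state totals.

Two weighting sources are supported: the printed published weighting
table (``rw_source="table2-fixed"``), and the spin-3/2 simulator with the
shipped calibrated environments (``rw_source="simulated"``).  The fixed
table makes the tissue-model predictions testable independently of the
simulator calibration.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .compartments import SodiumContributions, tissue_states

__all__ = [
    "PRINTED_RW",
    "RelativeSignalTable",
    "relative_contributions",
    "percent_signal_difference",
    "build_table3",
]

#: published per-compartment relaxation weightings (RW, signal relative to 1)
PRINTED_RW: dict[str, dict[str, float]] = {
    "NaDW": {"intra": 0.95, "extra": 0.95, "myelin": 0.85, "edema": 0.96},
    "NaPACMAN": {"intra": 0.35, "extra": 0.35, "myelin": 0.01, "edema": 0.40},
    "NaSIRFLA": {"intra": 0.45, "extra": 0.45, "myelin": 0.61, "edema": 0.10},
}

_COMPARTMENTS = ("intra", "extra", "myelin", "edema")


def relative_contributions(
    contribs: SodiumContributions,
    rw: dict[str, float],
    ref_intra_signal: float,
) -> dict[str, float]:
    """Per-compartment signal relative to the control intracellular signal.

    ``rw`` maps compartment name to relaxation weighting for one sequence;
    ``ref_intra_signal`` is ``q_intra(control) * RW[intra]`` of the same
    sequence.
    """
    if ref_intra_signal <= 0:
        raise ValueError("reference intracellular signal must be > 0")
    q = {
        "intra": contribs.q_intra,
        "extra": contribs.q_extra,
        "myelin": contribs.q_myelin,
        "edema": contribs.q_edema,
    }
    missing = [c for c in _COMPARTMENTS if c not in rw]
    if missing:
        raise KeyError(f"missing relaxation weighting for {missing}")
    return {c: q[c] * rw[c] / ref_intra_signal for c in _COMPARTMENTS}


def percent_signal_difference(total_state: float, total_control: float) -> float:
    """Percent signal difference of a tissue state vs control."""
    if total_control <= 0:
        raise ValueError("control total must be > 0")
    return 100.0 * (total_state / total_control - 1.0)


@dataclass(frozen=True)
class RelativeSignalTable:
    """Relative signal contributions for sequences x tissue states.

    ``rel[sequence][state][compartment]`` is normalized so that the
    control intracellular entry of each sequence is exactly 1.
    """

    rel: dict[str, dict[str, dict[str, float]]]
    total: dict[str, dict[str, float]]
    pct_diff: dict[str, dict[str, float]]

    def to_frame(self, printed_precision: bool = False) -> pd.DataFrame:
        """Tidy table mirroring the published layout (one row per
        sequence/state, compartment columns, total and percent
        difference)."""
        rows = []
        for seq, states in self.rel.items():
            for state, comps in states.items():
                row = {"sequence": seq, "tissue_state": state}
                for c, v in comps.items():
                    row[c] = round(v, 2) if printed_precision else v
                row["total"] = (
                    round(self.total[seq][state], 2)
                    if printed_precision
                    else self.total[seq][state]
                )
                pd_ = self.pct_diff[seq][state]
                if pd_ is not None:
                    row["pct_diff"] = round(pd_) if printed_precision else pd_
                rows.append(row)
        return pd.DataFrame(rows)


def build_table3(
    states: dict[str, SodiumContributions] | None = None,
    rw_source: str = "table2-fixed",
) -> RelativeSignalTable:
    """Full relative-signal table for 3 sequences x tissue states.

    ``rw_source="table2-fixed"`` uses the printed weightings verbatim;
    ``"simulated"`` runs the spin-3/2 simulator on the shipped calibrated
    environment defaults.
    """
    if states is None:
        states = tissue_states()
    if "control" not in states:
        raise ValueError("tissue states must include 'control'")

    if rw_source == "table2-fixed":
        rw_table = PRINTED_RW
    elif rw_source == "simulated":
        from .spin32 import relaxation_weighting_table

        rw_table = relaxation_weighting_table()
    else:
        raise ValueError(f"unknown rw_source {rw_source!r}")

    rel: dict[str, dict[str, dict[str, float]]] = {}
    total: dict[str, dict[str, float]] = {}
    pct: dict[str, dict[str, float]] = {}
    for seq, rw in rw_table.items():
        if seq not in PRINTED_RW:
            continue  # reference environments (csf, agar) have no tissue row
        ref = states["control"].q_intra * rw["intra"]
        rel[seq] = {}
        total[seq] = {}
        pct[seq] = {}
        for state, contribs in states.items():
            comps = relative_contributions(contribs, rw, ref)
            rel[seq][state] = comps
            total[seq][state] = sum(comps.values())
        for state in states:
            pct[seq][state] = percent_signal_difference(
                total[seq][state], total[seq]["control"]
            )
    return RelativeSignalTable(rel=rel, total=total, pct_diff=pct)
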