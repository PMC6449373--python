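"""Feed-forward cascade and transition readouts on induction time courses.

Four readouts quantify the reprogramming experiment:

* endogenous-vs-transgene expression: the NOTCH3-IC transgene lacks the
  3'UTR, so a 3'UTR probeset reports only the endogenous receptor while the
  CDS probeset also sees the transgene; their difference estimates the
  transgene-attributable signal.
* per-TF regulation calls over the two core regulatory circuitries (CRC):
  log2 fold change of induced versus matched control, thresholded into
  induced / repressed / unchanged and summarized as "k of n" counts.
* onset times: the earliest time point at which a gene's deviation from its
  baseline (day-0) value reaches a z threshold, in units of the within-gene
  sd of the series, with the sign persisting at all later time points.
* scenario classification from MES/ADRN signature score trajectories:
  transitioned, blocked (inhibitor prevented the switch) or reverted
  (induction too short to commit the cascade).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix
from .errors import InputError
from .simulate import Scenario

__all__ = [
    "CRCSets",
    "RegulationCall",
    "endogenous_expression",
    "regulation_summary",
    "onset_times",
    "classify_scenarios",
]


@dataclass(frozen=True)
class CRCSets:
    """The two disjoint core-regulatory-circuitry TF sets (18 ADRN, 20 MES)."""

    adrn_tfs: frozenset[str]
    mes_tfs: frozenset[str]

    def __post_init__(self) -> None:
        if self.adrn_tfs & self.mes_tfs:
            raise InputError("CRC TF sets must be disjoint")


@dataclass(frozen=True)
class RegulationCall:
    gene: str
    log2_fold_change: float
    call: str  # "induced" | "repressed" | "unchanged"


def endogenous_expression(
    expr: ExpressionMatrix, annot: pd.DataFrame, gene: str
) -> pd.DataFrame:
    """Endogenous signal of a gene and its transgene-attributable component.

    ``annot`` maps probeset -> (gene, region) with region in {CDS, 3UTR}.
    Returns a per-sample frame with ``endogenous`` (the 3'UTR probeset) and,
    when a CDS probeset exists, ``cds`` and ``transgene`` (= cds - 3'UTR).
    """

    rows = annot[annot["gene"] == gene]
    utr = rows.index[rows["region"] == "3UTR"]
    if len(utr) == 0:
        raise InputError(f"gene {gene!r} has no 3'UTR probeset")
    out = pd.DataFrame({"endogenous": expr.values.loc[utr[0]]})
    cds = rows.index[rows["region"] == "CDS"]
    if len(cds):
        out["cds"] = expr.values.loc[cds[0]]
        out["transgene"] = out["cds"] - out["endogenous"]
    return out


def regulation_summary(
    expr: ExpressionMatrix,
    crc: CRCSets,
    induced_samples: Sequence[str],
    control_samples: Sequence[str],
    lfc_threshold: float = 1.0,
    floor: float = 1.0,
) -> tuple[list[RegulationCall], dict[str, str]]:
    """Per-TF regulation calls and "k of n" counts for both CRC sets.

    The log2 fold change compares the mean of the induced samples with the
    mean of matched controls, flooring both means at ``floor`` linear units
    so Absent-call intensities cannot blow up the ratio.
    """

    if not induced_samples:
        raise InputError("no induced samples supplied")
    if not control_samples:
        raise InputError("no control samples supplied")
    induced = expr.subset_samples(induced_samples).values
    control = expr.subset_samples(control_samples).values
    tfs = sorted(crc.adrn_tfs | crc.mes_tfs)
    missing = [t for t in tfs if t not in expr.values.index]
    if missing:
        raise InputError(f"CRC TFs absent from matrix: {missing}")

    calls: list[RegulationCall] = []
    for tf in tfs:
        lfc = float(
            np.log2(
                max(induced.loc[tf].mean(), floor) / max(control.loc[tf].mean(), floor)
            )
        )
        if lfc >= lfc_threshold:
            call = "induced"
        elif lfc <= -lfc_threshold:
            call = "repressed"
        else:
            call = "unchanged"
        calls.append(RegulationCall(tf, lfc, call))

    def count(tf_set: frozenset[str], call: str) -> int:
        return sum(1 for c in calls if c.gene in tf_set and c.call == call)

    counts = {
        "adrn_repressed": f"{count(crc.adrn_tfs, 'repressed')} of {len(crc.adrn_tfs)}",
        "adrn_induced": f"{count(crc.adrn_tfs, 'induced')} of {len(crc.adrn_tfs)}",
        "mes_induced": f"{count(crc.mes_tfs, 'induced')} of {len(crc.mes_tfs)}",
        "mes_repressed": f"{count(crc.mes_tfs, 'repressed')} of {len(crc.mes_tfs)}",
    }
    return calls, counts


def onset_times(
    expr: ExpressionMatrix,
    genes: Iterable[str],
    z_threshold: float = 1.5,
) -> dict[str, float | None]:
    """First persistent departure from baseline, per gene, in onset days.

    Samples must carry a ``day`` metadata column and belong to a single
    trajectory (one sample per time point).  For each gene the series is
    standardized as z(t) = (x(t) - x(first day)) / sd(series); the onset is
    the earliest day with |z| >= threshold whose sign persists at every
    later day, else None.  Raising the threshold can only delay an onset.
    """

    days = expr.samples.get("day")
    if days is None or days.isna().any():
        raise InputError("samples must carry a numeric 'day' column")
    if days.duplicated().any():
        raise InputError("one sample per time point is required")
    if len(days) < 3:
        raise InputError("at least 3 time points are required")
    order = days.sort_values().index
    day_values = days.loc[order].to_numpy(dtype=float)

    out: dict[str, float | None] = {}
    for gene in genes:
        if gene not in expr.values.index:
            raise InputError(f"gene {gene!r} absent from matrix")
        x = expr.values.loc[gene, order].to_numpy(dtype=float)
        sd = x.std(ddof=1)
        if sd == 0:
            out[gene] = None
            continue
        z = (x - x[0]) / sd
        onset: float | None = None
        for i in range(1, len(z)):
            if abs(z[i]) >= z_threshold:
                sign = np.sign(z[i])
                if (np.sign(z[i:]) == sign).all():
                    onset = float(day_values[i])
                    break
        out[gene] = onset
    return out


def classify_scenarios(
    scores: pd.DataFrame,
    scenarios: Mapping[str, Scenario],
    margin: float = 0.0,
) -> dict[str, str]:
    """Verdict per scenario from its MES/ADRN score trajectory.

    ``scores`` needs columns ``scenario``, ``day``, ``mes_score``,
    ``adrn_score``.  A scenario *transitioned* when its final time point has
    mes_score - adrn_score > margin.  A scenario that did not transition is
    *blocked* when the inhibitor was active, else *reverted* (the induction
    was too short to commit the cascade, so the cells relaxed back; this
    label also covers scenarios whose induction never produced a
    transition).
    """

    required = {"scenario", "day", "mes_score", "adrn_score"}
    if not required <= set(scores.columns):
        raise InputError(f"scores frame must have columns {sorted(required)}")
    verdicts: dict[str, str] = {}
    for name, scen in scenarios.items():
        rows = scores[scores["scenario"] == name].sort_values("day")
        if rows.empty:
            raise InputError(f"scenario {name!r} has no score rows")
        final = rows.iloc[-1]
        if final[["mes_score", "adrn_score"]].isna().any():
            raise InputError(f"scenario {name!r} lacks scores at its final time point")
        if float(final["mes_score"] - final["adrn_score"]) > margin:
            verdicts[name] = "transitioned"
        elif scen.gsi_active:
            verdicts[name] = "blocked"
        else:
            verdicts[name] = "reverted"
    return verdicts
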