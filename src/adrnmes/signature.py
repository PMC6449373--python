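"""Lineage signature derivation and single-sample scoring.

Signatures are derived from isogenic MES/ADRN cell-line pairs: a gene joins
the MES list when, in at least ``min_pairs`` pairs, it (1) passes a per-pair
fold-change proxy for differential expression, (2) shows a minimum linear
intensity difference, (3) is detected (Present) in at least
``min_present_calls`` of the two pair members, and (4) is regulated in the
same direction in every pair it passes.  The ADRN list is symmetric, and a
gene with conflicting directions across passing pairs is excluded outright.

The primary single-sample score is rank-based: within a sample all N
probesets are rank-ordered ascending (ties get the average rank), each
signature gene's percentile is rank/N, and the score is the mean percentile
over the gene set.  Being rank-based it is invariant under any strictly
increasing per-sample transform of the intensities.  A summed z-score
variant is provided for time-course readouts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .containers import PRESENT, ExpressionMatrix
from .errors import InputError

__all__ = [
    "DerivationParams",
    "SignatureGeneSet",
    "derive_signature",
    "percentile_score",
    "score_panel",
    "zscore_matrix",
    "summed_zscore_score",
]


@dataclass(frozen=True)
class DerivationParams:
    """Selection thresholds for signature derivation.

    ``min_linear_diff`` lives on the linear intensity scale (a difference of
    100 is meaningful for MAS5-style intensities, not for log2 values).
    ``per_pair_fold_change`` is the fold-change proxy standing in for a
    per-pair significance test: with one sample per condition per pair there
    is no replicate structure to support a test statistic.
    """

    min_pairs: int = 3
    min_linear_diff: float = 100.0
    min_present_calls: int = 1
    per_pair_fold_change: float = 2.0
    ratio_floor: float = 1.0

    def __post_init__(self) -> None:
        if min(self.min_pairs, self.min_present_calls) < 1:
            raise InputError("min_pairs and min_present_calls must be >= 1")
        if self.min_linear_diff <= 0 or self.per_pair_fold_change <= 0:
            raise InputError("thresholds must be positive")


@dataclass
class SignatureGeneSet:
    """Two disjoint directional gene lists with per-gene selection evidence.

    ``evidence`` is indexed by gene id with columns ``direction``
    (``MES``/``ADRN``), ``pairs_passed`` and one ``diff_<pair>`` column per
    pair holding the MES-minus-ADRN linear difference.
    """

    mes_genes: frozenset[str]
    adrn_genes: frozenset[str]
    evidence: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if self.mes_genes & self.adrn_genes:
            raise InputError("MES and ADRN signature sets must be disjoint")


def _pairs_of(panel: ExpressionMatrix, min_pairs: int) -> dict[str, tuple[str, str]]:
    """Map pair_id -> (MES sample, ADRN sample); validates pairing structure."""
    pairs: dict[str, tuple[str, str]] = {}
    with_pair = panel.samples.dropna(subset=["pair_id"])
    for pid, grp in with_pair.groupby("pair_id"):
        if len(grp) != 2 or set(grp["lineage"]) != {"MES", "ADRN"}:
            raise InputError(
                f"pair {pid!r} must have exactly one MES and one ADRN sample"
            )
        mes = grp.index[grp["lineage"] == "MES"][0]
        adrn = grp.index[grp["lineage"] == "ADRN"][0]
        pairs[str(pid)] = (mes, adrn)
    if len(pairs) < min_pairs:
        raise InputError(
            f"need at least {min_pairs} complete isogenic pairs, found {len(pairs)}"
        )
    return pairs


def derive_signature(
    panel: ExpressionMatrix, params: DerivationParams | None = None
) -> SignatureGeneSet:
    """Derive the MES/ADRN signature from a panel of isogenic pairs.

    Per pair and gene, the pair is "passed" when the fold change (with a
    small floor on the denominator), the linear difference and the detection
    criteria all hold.  A gene is selected when it passes >= ``min_pairs``
    pairs, all in the same direction; passing pairs in both directions
    disqualify the gene (inconsistent regulation).
    """

    params = params or DerivationParams()
    pairs = _pairs_of(panel, params.min_pairs)

    values = panel.values
    present = panel.detection == PRESENT
    n_genes = values.shape[0]
    passed_mes = np.zeros(n_genes, dtype=int)
    passed_adrn = np.zeros(n_genes, dtype=int)
    diffs: dict[str, np.ndarray] = {}
    for pid, (mes_s, adrn_s) in sorted(pairs.items()):
        mes_v = values[mes_s].to_numpy()
        adrn_v = values[adrn_s].to_numpy()
        diff = mes_v - adrn_v
        hi = np.maximum(mes_v, adrn_v)
        lo = np.maximum(np.minimum(mes_v, adrn_v), params.ratio_floor)
        fold_ok = hi / lo >= params.per_pair_fold_change
        diff_ok = np.abs(diff) >= params.min_linear_diff
        det_ok = (
            present[mes_s].to_numpy().astype(int) + present[adrn_s].to_numpy().astype(int)
        ) >= params.min_present_calls
        ok = fold_ok & diff_ok & det_ok
        passed_mes += ok & (diff > 0)
        passed_adrn += ok & (diff < 0)
        diffs[pid] = diff

    consistent_mes = (passed_mes >= params.min_pairs) & (passed_adrn == 0)
    consistent_adrn = (passed_adrn >= params.min_pairs) & (passed_mes == 0)
    index = values.index
    mes_genes = frozenset(index[consistent_mes])
    adrn_genes = frozenset(index[consistent_adrn])

    selected = consistent_mes | consistent_adrn
    evidence = pd.DataFrame(
        {
            "direction": np.where(consistent_mes, "MES", "ADRN")[selected],
            "pairs_passed": np.where(consistent_mes, passed_mes, passed_adrn)[selected],
            **{f"diff_{pid}": d[selected] for pid, d in sorted(diffs.items())},
        },
        index=index[selected],
    )
    return SignatureGeneSet(mes_genes, adrn_genes, evidence)


def _percentile_grid(expr: ExpressionMatrix) -> np.ndarray:
    """Per-sample percentiles rank/N with average-rank ties (genes x samples)."""
    vals = expr.values.to_numpy()
    n = vals.shape[0]
    ranks = rankdata(vals, axis=0)
    return ranks / n


def percentile_score(expr: ExpressionMatrix, genes: Iterable[str]) -> pd.Series:
    """Mean within-sample expression percentile of a gene set, per sample.

    Percentiles are computed relative to the full probeset list of the
    matrix, so scores are comparable across samples; each score lies in
    [1/N, 1].
    """

    gene_list = list(genes)
    if not gene_list:
        raise InputError("gene set is empty")
    if expr.values.shape[0] < 2:
        raise InputError("expression matrix must contain at least 2 probesets")
    missing = [g for g in gene_list if g not in expr.values.index]
    if missing:
        raise InputError(f"genes absent from matrix: {sorted(missing)}")
    perc = _percentile_grid(expr)
    locs = expr.values.index.get_indexer(gene_list)
    sub = perc[locs, :]
    # per-sample contiguous 1-D reductions: the score is reproducible to the
    # last bit by any straightforward mean over the same percentile vector
    scores = np.array(
        [float(np.mean(np.ascontiguousarray(sub[:, j]))) for j in range(sub.shape[1])]
    )
    return pd.Series(scores, index=expr.values.columns, name="score")


def score_panel(expr: ExpressionMatrix, sig: SignatureGeneSet) -> pd.DataFrame:
    """MES and ADRN percentile scores per sample, in input sample order."""
    if not sig.mes_genes or not sig.adrn_genes:
        raise InputError("both signature gene sets must be non-empty")
    mes = percentile_score(expr, sorted(sig.mes_genes))
    adrn = percentile_score(expr, sorted(sig.adrn_genes))
    return pd.DataFrame({"mes_score": mes, "adrn_score": adrn})


def zscore_matrix(expr: ExpressionMatrix, subset: Iterable[str]) -> pd.DataFrame:
    """Per-gene z-scores (sample sd, ddof=1) across the provided samples."""
    gene_list = list(subset)
    if not gene_list:
        raise InputError("gene set is empty")
    missing = [g for g in gene_list if g not in expr.values.index]
    if missing:
        raise InputError(f"genes absent from matrix: {sorted(missing)}")
    sub = expr.values.loc[gene_list]
    sd = sub.std(axis=1, ddof=1)
    flat = sd[(sd == 0) | sd.isna()]
    if len(flat):
        raise InputError(
            f"zero-variance genes cannot be z-scored: {sorted(flat.index)}"
        )
    return sub.sub(sub.mean(axis=1), axis=0).div(sd, axis=0)


def summed_zscore_score(expr: ExpressionMatrix, genes: Iterable[str]) -> pd.Series:
    """Per-sample sum of z-scores over a gene set (the Fig.-style summed score)."""
    z = zscore_matrix(expr, genes)
    out = z.sum(axis=0)
    out.name = "summed_z"
    return out
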