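"""Paired daughter-cell asymmetry calling from single-cell count tables.

Input is a gene x cell count matrix from plate-based scRNA-seq of sister
daughter cells (two cells per pair), with ERCC spike-in rows for
normalization.  The pipeline is:

1. ``qc_filter`` — keep cells with more than ``min_genes`` detected genes
   and at most ``max_mito`` mitochondrial read fraction; any pair losing
   a member is dropped entirely so that only complete pairs remain.
2. ``ercc_normalize`` — per-cell size factors from ERCC spike-in totals
   (anchored at the geometric mean), so that equal spiked-in amounts map
   to equal normalized totals.
3. ``pair_asymmetry_call`` — per queried gene, the fold ratio (max/min of
   the two normalized values) within each pair; a pair is asymmetric if
   ANY queried gene reaches the 1.5-fold cutoff.
4. ``summarize_pairs`` — asymmetric/symmetric fractions with Wilson CI.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PairTable",
    "PairCall",
    "QCReport",
    "NormalizationResult",
    "PairSummary",
    "qc_filter",
    "ercc_normalize",
    "pair_asymmetry_call",
    "summarize_pairs",
    "ERCC_PREFIX",
    "PAIR_CUTOFF",
]

ERCC_PREFIX = "ERCC-"
#: Fold-change cutoff for calling a gene asymmetric within a pair.
PAIR_CUTOFF = 1.5


@dataclass
class PairTable:
    """Gene x cell counts with spike-in rows and pair annotations.

    counts : DataFrame, rows = genes (+ ERCC spike-ins, prefixed
        ``ERCC-``), columns = cells, nonnegative integers
    cell_meta : DataFrame indexed by cell id with columns ``pair_id``,
        ``genes_detected``, ``mito_fraction``
    """

    counts: pd.DataFrame
    cell_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be nonnegative")
        missing = set(self.counts.columns) ^ set(self.cell_meta.index)
        if missing:
            raise ValueError(f"counts/metadata cell mismatch: {sorted(missing)[:5]}")
        need = {"pair_id", "genes_detected", "mito_fraction"}
        if not need <= set(self.cell_meta.columns):
            raise ValueError(f"cell_meta must have columns {sorted(need)}")
        sizes = self.cell_meta.groupby("pair_id").size()
        bad = sizes[sizes != 2]
        if len(bad):
            raise ValueError(f"pairs without exactly 2 cells: {list(bad.index)[:5]}")
        self.cell_meta = self.cell_meta.loc[self.counts.columns]

    @property
    def ercc_rows(self) -> pd.Index:
        return self.counts.index[self.counts.index.str.startswith(ERCC_PREFIX)]

    @property
    def gene_rows(self) -> pd.Index:
        return self.counts.index[~self.counts.index.str.startswith(ERCC_PREFIX)]

    @property
    def n_pairs(self) -> int:
        return self.cell_meta["pair_id"].nunique()

    def pairs(self) -> dict[object, list[str]]:
        return {pid: list(grp.index)
                for pid, grp in self.cell_meta.groupby("pair_id")}


@dataclass
class QCReport:
    n_cells_in: int
    n_cells_kept: int
    dropped_cells: pd.DataFrame  # cell_id, reason
    dropped_pairs: list
    empty: bool = False


def qc_filter(table: PairTable, min_genes: int = 10_000,
              max_mito: float = 0.05) -> tuple[PairTable, QCReport]:
    """Quality-filter cells and preserve pairing integrity.

    Keeps cells with strictly more than ``min_genes`` detected genes and a
    mitochondrial read fraction of at most ``max_mito`` (cells strictly
    above the threshold are eliminated).  A pair that loses either member
    is dropped entirely.
    """
    meta = table.cell_meta
    reasons = []
    for cell, row in meta.iterrows():
        why = []
        if not row["genes_detected"] > min_genes:
            why.append(f"genes_detected <= {min_genes}")
        if row["mito_fraction"] > max_mito:
            why.append(f"mito_fraction > {max_mito}")
        if why:
            reasons.append({"cell_id": cell, "reason": "; ".join(why)})
    dropped = pd.DataFrame(reasons, columns=["cell_id", "reason"])
    failed = set(dropped["cell_id"])
    broken_pairs = sorted(
        {meta.loc[c, "pair_id"] for c in failed})
    keep_cells = [c for c in meta.index
                  if meta.loc[c, "pair_id"] not in broken_pairs]
    report = QCReport(
        n_cells_in=len(meta),
        n_cells_kept=len(keep_cells),
        dropped_cells=dropped,
        dropped_pairs=broken_pairs,
        empty=len(keep_cells) == 0,
    )
    if report.empty:
        return table, report  # caller decides; flagged rather than raising
    out = PairTable(counts=table.counts[keep_cells],
                    cell_meta=meta.loc[keep_cells])
    return out, report


@dataclass
class NormalizationResult:
    normalized: pd.DataFrame  # counts / size factor (genes + ERCC rows)
    size_factors: pd.Series
    excluded_cells: list = field(default_factory=list)


def ercc_normalize(table: PairTable) -> NormalizationResult:
    """Per-cell size factors from ERCC spike-in totals.

    size_factor(cell) = ERCC total / geometric mean of ERCC totals;
    normalized value = count / size_factor.  Since every cell received
    the same spike-in amount, normalized ERCC totals are equal across
    cells.  Cells with a zero ERCC total cannot be normalized and are
    excluded (flagged).
    """
    if len(table.ercc_rows) == 0:
        raise ValueError("no ERCC spike-in rows (prefix 'ERCC-') found")
    totals = table.counts.loc[table.ercc_rows].sum(axis=0).astype(float)
    excluded = list(totals.index[totals <= 0])
    ok = totals.index[totals > 0]
    log_gm = np.log(totals[ok]).mean()
    sf = totals[ok] / math.exp(log_gm)
    normalized = table.counts[ok].astype(float).div(sf, axis=1)
    return NormalizationResult(normalized=normalized, size_factors=sf,
                               excluded_cells=excluded)


@dataclass
class PairCall:
    pair_id: object
    ratios: dict[str, float]  # gene -> max/min ratio (NaN if undefined)
    label: str  # "asymmetric" | "symmetric"
    rule: str
    cutoff: float
    n_genes_defined: int


def pair_asymmetry_call(
    normalized: pd.DataFrame,
    cell_meta: pd.DataFrame,
    genes: list[str] = ("H3f3a", "H3f3b"),
    cutoff: float = PAIR_CUTOFF,
    rule: str = "any",
    pseudocount: float = 1.0,
) -> list[PairCall]:
    """Call each daughter pair asymmetric or symmetric for the query genes.

    Per gene, the ratio is max/min of the two normalized values; when
    either member is below one normalized unit, the pseudocount is added
    to both before forming the ratio (avoids infinite ratios at
    dropouts).  A gene with both members at zero is undefined for that
    pair and excluded from the rule.  ``rule="any"`` labels the pair
    asymmetric when any queried gene reaches the cutoff; ``rule="all"``
    requires every defined gene to reach it.
    """
    if rule not in ("any", "all"):
        raise ValueError("rule must be 'any' or 'all'")
    genes = list(genes)
    missing = [g for g in genes if g not in normalized.index]
    if missing:
        raise KeyError(f"genes not present in matrix: {missing}")
    calls = []
    for pid, grp in cell_meta.groupby("pair_id"):
        cells = list(grp.index)
        if len(cells) != 2 or any(c not in normalized.columns for c in cells):
            raise ValueError(f"pair {pid!r} is not intact in the matrix")
        ratios = {}
        for g in genes:
            a, b = float(normalized.at[g, cells[0]]), float(normalized.at[g, cells[1]])
            if a == 0.0 and b == 0.0:
                ratios[g] = float("nan")
                continue
            if min(a, b) < 1.0:
                a, b = a + pseudocount, b + pseudocount
            ratios[g] = max(a, b) / min(a, b)
        defined = [r for r in ratios.values() if not math.isnan(r)]
        hits = [r >= cutoff for r in defined]
        if not defined:
            label = "symmetric"  # no evidence for asymmetry
        elif rule == "any":
            label = "asymmetric" if any(hits) else "symmetric"
        else:
            label = "asymmetric" if all(hits) else "symmetric"
        calls.append(PairCall(pair_id=pid, ratios=ratios, label=label,
                              rule=rule, cutoff=cutoff,
                              n_genes_defined=len(defined)))
    return calls


@dataclass
class PairSummary:
    n_pairs: int
    n_asymmetric: int
    fraction_asymmetric: float
    fraction_symmetric: float
    ci95: tuple[float, float]  # Wilson interval for the asymmetric fraction


def summarize_pairs(calls: list[PairCall]) -> PairSummary:
    """Asymmetric/symmetric fractions over pairs with a Wilson 95% CI."""
    if not calls:
        raise ValueError("need at least one pair call")
    from statsmodels.stats.proportion import proportion_confint

    n = len(calls)
    k = sum(c.label == "asymmetric" for c in calls)
    lo, hi = proportion_confint(k, n, alpha=0.05, method="wilson")
    return PairSummary(
        n_pairs=n,
        n_asymmetric=k,
        fraction_asymmetric=k / n,
        fraction_symmetric=1.0 - k / n,
        ci95=(float(lo), float(hi)),
    )
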