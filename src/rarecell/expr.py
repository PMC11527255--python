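"""Single-cell expression analysis: differential expression, survivor-set
derivation, per-cell enrichment scoring, and over-representation analysis.

The core question is whether tumor cells that survive different
chemotherapies in different cell lines converge on a shared transcriptional
program.  Differential expression is tested per condition-vs-control
contrast with a negative-binomial log-linear model that includes the
per-cell detection rate (fraction of genes detected) and sequencing batch
as covariates — the detection rate absorbs the strong technical variation
in single-cell library complexity.  Genes up-regulated past log2
fold-change and FDR thresholds in every contrast form the "survivor" gene
set, which is then scored per cell with a rank-based enrichment score and
tested against curated collections by hypergeometric over-representation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CountMatrix",
    "GeneSet",
    "DEResult",
    "normalize_log",
    "detection_rate",
    "differential_expression",
    "shared_upregulated",
    "lfc_concordance",
    "jasmine_score",
    "ora_enrichment",
    "read_gmt",
    "write_gmt",
]


@dataclass
class CountMatrix:
    """Genes x cells integer counts with per-cell metadata.

    ``meta`` must contain one row per cell with at least columns
    ``cell_id``, ``line``, ``condition``, ``batch``.
    """

    counts: np.ndarray
    gene_ids: list[str]
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-D (genes x cells)")
        if len(self.gene_ids) != self.counts.shape[0]:
            raise ValueError("gene_ids length must match number of rows")
        if len(self.meta) != self.counts.shape[1]:
            raise ValueError("metadata must cover every cell")
        if (self.counts < 0).any():
            raise ValueError("negative counts")
        for col in ("cell_id", "line", "condition", "batch"):
            if col not in self.meta.columns:
                raise ValueError(f"metadata missing column {col!r}")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def subset_cells(self, mask: np.ndarray) -> "CountMatrix":
        return CountMatrix(
            counts=self.counts[:, mask],
            gene_ids=self.gene_ids,
            meta=self.meta.loc[mask].reset_index(drop=True),
        )


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene identifiers (unique, order preserved)."""

    name: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        seen: dict[str, None] = {}
        for g in self.genes:
            seen.setdefault(g, None)
        object.__setattr__(self, "genes", tuple(seen))

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, g: str) -> bool:
        return g in set(self.genes)


@dataclass
class DEResult:
    """Per-gene differential-expression results for one contrast.

    ``table`` columns: gene, lfc (log2), p_value, fdr, mean_expr,
    det_rate_case, det_rate_control, tested.  Untested genes (zero counts
    on both sides) keep NaN statistics and ``tested = False``.
    """

    contrast: str
    table: pd.DataFrame

    def selected(self, lfc_min: float = 1.5, fdr_max: float = 0.01) -> set[str]:
        """Genes up-regulated past the log2-LFC and FDR thresholds."""
        t = self.table
        keep = t["tested"] & (t["lfc"] > lfc_min) & (t["fdr"] < fdr_max)
        return set(t.loc[keep, "gene"])


def detection_rate(counts: np.ndarray) -> np.ndarray:
    """Fraction of genes with count > 0, per cell."""
    return (np.asarray(counts) > 0).mean(axis=0)


def normalize_log(cm: CountMatrix, scale: float | None = None) -> np.ndarray:
    """Library-size normalize each cell to a common scale, then log2(1+x).

    The common scale defaults to the median library size; the output is
    invariant to doubling the scale factor only up to the additive log
    shift, but proportional cells map to identical vectors, which is what
    rank-based downstream scoring needs.
    """
    counts = cm.counts.astype(float)
    libsize = counts.sum(axis=0)
    zero = np.flatnonzero(libsize == 0)
    if zero.size:
        ids = [cm.meta["cell_id"].iloc[i] for i in zero]
        raise ValueError(f"all-zero cells: {ids}")
    if scale is None:
        scale = float(np.median(libsize))
    return np.log2(1.0 + counts / libsize * scale)


def _size_factors(
    counts: np.ndarray,
    trim_m: float = 0.3,
    trim_a: float = 0.05,
    exclude: np.ndarray | None = None,
) -> np.ndarray:
    """TMM-style effective library sizes (composition-robust depth).

    Total counts are a biased depth estimate when a large, asymmetric
    gene fraction is differentially expressed: the shifted genes inflate
    one group's libraries and drag every other gene's fold-change with
    them.  Per cell, the trimmed mean of log expression ratios (M) against
    a pseudo-reference — trimming the ``trim_m`` tails of M and the
    ``trim_a`` tails of average abundance — estimates the depth from the
    non-DE bulk.  Genes flagged in ``exclude`` (e.g. DE genes found in a
    first pass) are left out of the pool entirely.  Falls back to total
    counts when too few genes remain.
    """
    counts = np.asarray(counts, dtype=float)
    libsize = np.maximum(counts.sum(axis=0), 1.0)
    log_cpm = np.log(counts + 0.5) - np.log(libsize)[None, :]
    pool = np.ones(counts.shape[0], dtype=bool)
    if exclude is not None:
        pool &= ~np.asarray(exclude, dtype=bool)
    ref = log_cpm[:, :].mean(axis=1)
    factors = np.ones(counts.shape[1])
    for c in range(counts.shape[1]):
        detected = (counts[:, c] > 0) & pool
        if detected.sum() < 50:
            continue
        m = log_cpm[detected, c] - ref[detected]
        a = (log_cpm[detected, c] + ref[detected]) / 2.0
        lo_m, hi_m = np.quantile(m, [trim_m, 1 - trim_m])
        lo_a, hi_a = np.quantile(a, [trim_a, 1 - trim_a])
        keep = (m >= lo_m) & (m <= hi_m) & (a >= lo_a) & (a <= hi_a)
        if keep.sum() >= 20:
            factors[c] = np.exp(m[keep].mean())
    sf = libsize * factors
    return sf / np.exp(np.mean(np.log(sf))) * np.exp(np.mean(np.log(libsize)))


def _check_confounding(group: np.ndarray, batch: np.ndarray) -> None:
    tab = pd.crosstab(pd.Series(batch), pd.Series(group))
    if tab.shape[1] < 2:
        raise ValueError("contrast has a single group")
    # every batch that appears must not be exclusive to one group,
    # unless at least one batch mixes both (then the design is estimable)
    mixed = (tab > 0).sum(axis=1) == 2
    if not mixed.any():
        aliased = tab.index.tolist()
        raise ValueError(
            f"batch is confounded with the contrast (no batch contains both "
            f"groups; batches: {aliased})"
        )


def _moment_dispersions(counts: np.ndarray, group: np.ndarray, offset: np.ndarray) -> np.ndarray:
    """Per-gene NB dispersion (alpha in var = mu + alpha mu^2), shrunk.

    Raw per-gene alphas come from the method of moments on offset-adjusted
    counts within each group (so the contrast itself does not inflate the
    estimate); they are then shrunk on the log scale toward a quadratic
    mean-dispersion trend, stabilizing genes with few counts.
    """
    y = counts / np.exp(offset)[None, :]  # counts per unit offset
    alphas = np.zeros(counts.shape[0])
    denom = np.zeros(counts.shape[0])
    for g in np.unique(group):
        sub = y[:, group == g]
        sf = np.exp(offset)[group == g]
        mu = sub.mean(axis=1)
        # var of raw counts about mu*sf, moment equation var = mu*sf + a*(mu*sf)^2
        raw = counts[:, group == g]
        m = mu[:, None] * sf[None, :]
        resid2 = (raw - m) ** 2
        num = (resid2 - m).sum(axis=1)
        den = (m**2).sum(axis=1)
        alphas += np.maximum(num, 0.0)
        denom += den
    raw_alpha = np.where(denom > 0, alphas / np.maximum(denom, 1e-12), 0.0)
    raw_alpha = np.clip(raw_alpha, 1e-6, 10.0)

    logmu = np.log(counts.mean(axis=1) + 1e-8)
    X = np.column_stack([np.ones_like(logmu), logmu, logmu**2])
    la = np.log(raw_alpha)
    beta, *_ = np.linalg.lstsq(X, la, rcond=None)
    trend = np.clip(np.exp(X @ beta), 1e-6, 10.0)
    # geometric-mean shrinkage toward the trend
    w = 0.6
    return np.exp(w * np.log(trend) + (1 - w) * np.log(raw_alpha))


def _fit_all_genes(
    counts: np.ndarray,
    X_full: np.ndarray,
    X_null: np.ndarray,
    offset: np.ndarray,
    alphas: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-gene NB GLM fits; returns (lfc_log2, p_value, tested)."""
    n_genes = counts.shape[0]
    lfc = np.full(n_genes, np.nan)
    pval = np.full(n_genes, np.nan)
    tested = np.zeros(n_genes, dtype=bool)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for g in range(n_genes):
            y = counts[g]
            if y.sum() == 0:
                continue
            fam = sm.families.NegativeBinomial(alpha=float(alphas[g]))
            try:
                full = sm.GLM(y, X_full, family=fam, offset=offset).fit(maxiter=100)
                null = sm.GLM(y, X_null, family=fam, offset=offset).fit(maxiter=100)
            except Exception:
                continue
            llr = 2.0 * (full.llf - null.llf)
            pval[g] = stats.chi2.sf(max(llr, 0.0), df=1)
            lfc[g] = full.params[1] / np.log(2.0)
            tested[g] = True
    return lfc, pval, tested


def differential_expression(
    cm: CountMatrix,
    condition: str,
    control: str,
    line: str | None = None,
    min_cells: int = 3,
    normalization_passes: int = 2,
) -> DEResult:
    """Negative-binomial DE for one condition-vs-control contrast.

    Fits, per gene, an NB log-linear model with the condition indicator,
    the centered per-cell detection rate, and batch dummies, with the log
    effective library size (TMM) as offset, and tests the condition term
    by likelihood ratio against a chi-square(1).  Dispersions are moment
    estimates shrunk toward a mean-dispersion trend and held fixed during
    fitting.  With ``normalization_passes = 2`` (default) the genes found
    DE in a first pass are excluded from the size-factor pool and the
    model is refit — removing the residual composition bias that a large
    one-sided DE fraction leaves even in trimmed normalization.
    P-values are BH-adjusted; ``lfc`` is the condition coefficient on the
    log2 scale.  Genes with zero counts on both sides are excluded from
    testing and flagged (``tested = False``).
    """
    meta = cm.meta
    mask = meta["condition"].isin([condition, control]).to_numpy()
    if line is not None:
        mask &= (meta["line"] == line).to_numpy()
    sub = cm.subset_cells(mask)
    group = (sub.meta["condition"] == condition).to_numpy().astype(int)
    if (group == 1).sum() < min_cells or (group == 0).sum() < min_cells:
        raise ValueError(f"need >= {min_cells} cells per side of the contrast")
    _check_confounding(group, sub.meta["batch"].to_numpy())

    counts = sub.counts.astype(float)
    det = detection_rate(counts)
    det_c = det - det.mean()

    batch = pd.get_dummies(sub.meta["batch"], drop_first=True, dtype=float)
    X_full = np.column_stack(
        [np.ones(sub.n_cells), group.astype(float), det_c, batch.to_numpy()]
    )
    X_null = np.delete(X_full, 1, axis=1)
    # drop aliased columns (e.g. a batch dummy collinear with the rest)
    def prune(X: np.ndarray) -> np.ndarray:
        q, r = np.linalg.qr(X)
        keep = np.abs(np.diag(r)) > 1e-8
        return X[:, keep]

    if np.linalg.matrix_rank(X_full) < X_full.shape[1]:
        X_full = prune(X_full)
        X_null = prune(X_null)

    n_genes = sub.n_genes
    case, ctrl = group == 1, group == 0
    det_case = (counts[:, case] > 0).mean(axis=1)
    det_ctrl = (counts[:, ctrl] > 0).mean(axis=1)
    mean_expr = counts.mean(axis=1)

    exclude = None
    for fit_pass in range(max(normalization_passes, 1)):
        offset = np.log(_size_factors(counts, exclude=exclude))
        alphas = _moment_dispersions(counts, group, offset)
        lfc, pval, tested = _fit_all_genes(counts, X_full, X_null, offset, alphas)
        if fit_pass == normalization_passes - 1 or not tested.any():
            break
        fdr_pass = np.full(n_genes, 1.0)
        fdr_pass[tested] = multipletests(pval[tested], method="fdr_bh")[1]
        de_mask = (fdr_pass < 0.05) & (np.nan_to_num(np.abs(lfc)) > 0.5)
        if de_mask.sum() == 0 or de_mask.sum() > 0.5 * n_genes:
            break  # nothing to refine, or too few genes left to normalize on
        exclude = de_mask

    fdr = np.full(n_genes, np.nan)
    if tested.any():
        fdr[tested] = multipletests(pval[tested], method="fdr_bh")[1]

    table = pd.DataFrame(
        {
            "gene": sub.gene_ids,
            "lfc": lfc,
            "p_value": pval,
            "fdr": fdr,
            "mean_expr": mean_expr,
            "det_rate_case": det_case,
            "det_rate_control": det_ctrl,
            "tested": tested,
        }
    )
    name = f"{line + ':' if line else ''}{condition}_vs_{control}"
    return DEResult(contrast=name, table=table)


def shared_upregulated(
    results: list[DEResult],
    lfc_min: float = 1.5,
    fdr_max: float = 0.01,
    name: str = "shared_upregulated",
) -> GeneSet:
    """Intersection of up-regulated genes across contrasts.

    Each contrast contributes its ``lfc > lfc_min and fdr < fdr_max``
    selection; the returned set is their intersection, so it is empty as
    soon as any single contrast selects nothing.  Order of the inputs does
    not matter.
    """
    if len(results) < 2:
        raise ValueError("need at least 2 DE results to intersect")
    universes = [set(r.table["gene"]) for r in results]
    common = set.intersection(*universes)
    if not common:
        raise ValueError("DE results share no genes")
    selections = [r.selected(lfc_min, fdr_max) for r in results]
    shared = set.intersection(*selections) if selections else set()
    ordered = [g for g in results[0].table["gene"] if g in shared]
    return GeneSet(name=name, genes=tuple(ordered))


def lfc_concordance(r1: DEResult, r2: DEResult, genes: GeneSet) -> float:
    """Pearson correlation of log2 fold-changes over a gene set."""
    t1 = r1.table.set_index("gene")["lfc"]
    t2 = r2.table.set_index("gene")["lfc"]
    gs = [g for g in genes.genes if g in t1.index and g in t2.index]
    if len(gs) < 3:
        raise ValueError("need at least 3 genes for a correlation")
    a, b = t1.loc[gs].to_numpy(), t2.loc[gs].to_numpy()
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 3:
        raise ValueError("fewer than 3 genes with finite LFCs in both results")
    return float(np.corrcoef(a[ok], b[ok])[0, 1])


def _minmax(x: np.ndarray) -> np.ndarray:
    lo, hi = x.min(), x.max()
    if hi - lo < 1e-12:
        return np.full_like(x, 0.5)
    return (x - lo) / (hi - lo)


def jasmine_score(
    norm: np.ndarray, gene_ids: list[str], gs: GeneSet
) -> pd.DataFrame:
    """Rank-based per-cell gene-set enrichment score in [0, 1].

    For each cell, two components are computed over *expressed* genes
    (value > 0): (i) the mean rank of expressed signature genes among all
    expressed genes, divided by the number of expressed genes — invariant
    under any monotone transform of expression; (ii) the odds ratio of
    signature-gene detection versus non-signature detection.  Each
    component is min-max scaled across cells (a degenerate all-equal
    component maps to 0.5) and the final score is their arithmetic mean.
    A cell expressing no signature gene gets rank component 0.

    Returns a DataFrame with columns ``rank_component``, ``or_component``,
    ``score`` (one row per cell).
    """
    norm = np.asarray(norm, dtype=float)
    idx = [i for i, g in enumerate(gene_ids) if g in gs]
    if not idx:
        raise ValueError("gene set does not intersect the matrix genes")
    sig = np.zeros(norm.shape[0], dtype=bool)
    sig[idx] = True

    n_cells = norm.shape[1]
    rank_comp = np.zeros(n_cells)
    or_comp = np.zeros(n_cells)
    for c in range(n_cells):
        v = norm[:, c]
        expressed = v > 0
        n_expr = int(expressed.sum())
        sig_expr = expressed & sig
        k = int(sig_expr.sum())
        if n_expr > 0 and k > 0:
            ranks = stats.rankdata(v[expressed], method="average")
            rank_comp[c] = ranks[sig[expressed]].mean() / n_expr
        # detection odds ratio; empty margins floored at 1 to stay finite
        se = k
        sn = int(sig.sum()) - k
        ne = n_expr - k
        nn = int((~sig).sum()) - ne
        or_comp[c] = (se * max(nn, 1)) / (max(sn, 1) * max(ne, 1))

    rank_s = _minmax(rank_comp)
    or_s = _minmax(or_comp)
    return pd.DataFrame(
        {
            "rank_component": rank_s,
            "or_component": or_s,
            "score": (rank_s + or_s) / 2.0,
        }
    )


def ora_enrichment(
    query: GeneSet, collections: list[GeneSet], universe: list[str]
) -> pd.DataFrame:
    """Hypergeometric over-representation of a query set in collections.

    For each collection, the upper-tail probability of observing at least
    the achieved overlap when drawing ``|query|`` genes from the universe
    without replacement; BH adjustment across collections.  Collections
    disjoint from the universe are skipped with a warning.
    """
    uni = set(universe)
    q = set(query.genes) & uni
    if not q:
        raise ValueError("query does not intersect the universe")
    rows = []
    for coll in collections:
        members = set(coll.genes) & uni
        if not members:
            warnings.warn(f"collection {coll.name!r} disjoint from universe; skipped")
            continue
        k = len(q & members)
        # P(X >= k), X ~ Hypergeom(N=|U|, K=|coll|, n=|q|)
        p = float(stats.hypergeom.sf(k - 1, len(uni), len(members), len(q)))
        rows.append(
            {"collection": coll.name, "overlap": k, "size": len(members), "p_value": p}
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["fdr"] = multipletests(out["p_value"], method="fdr_bh")[1]
        out = out.sort_values("p_value", kind="mergesort").reset_index(drop=True)
    return out


def read_gmt(path) -> list[GeneSet]:
    """Read a GMT gene-set collection (name, description, members...)."""
    sets = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets.append(GeneSet(name=parts[0], genes=tuple(parts[2:])))
    return sets


def write_gmt(sets: list[GeneSet], path) -> None:
    with open(path, "w") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, "na", *gs.genes]) + "\n")
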