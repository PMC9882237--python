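"""Pooled-screen count ingestion, normalization and scoring.

The pipeline starts at a MAGeCK-style guide count table (sgRNA, gene, one
column per sample) plus a sample sheet labeling each sample as T0,
untreated or treated. Guides are trimmed (bottom 5% by total raw count,
plus miRNA-targeting guides), sequencing depth is normalized against the
distribution of the non-targeting guides, and guide-level log2 fold
changes are collapsed to gene level by the mean. Non-targeting guides are
randomly grouped into library-sized "pseudo-genes" that provide the
empirical null for z-scoring, bootstrap p-values and Benjamini-Hochberg
FDR control.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

NONTARGETING = "NONTARGETING"
CONDITIONS = ("T0", "untreated", "treated")

__all__ = [
    "NONTARGETING",
    "CountMatrix",
    "read_counts",
    "write_counts",
    "filter_guides",
    "normalize_depth",
    "compute_l2fc",
    "collapse_genes",
    "make_pseudo_genes",
    "score_vs_null",
    "concordance_test",
    "ConcordanceResult",
]


@dataclass
class CountMatrix:
    """Guide count matrix with annotation and sample metadata.

    Attributes
    ----------
    counts : DataFrame
        Raw (or, after :func:`normalize_depth`, depth-normalized)
        guide x sample table, indexed by sgRNA id.
    guides : DataFrame
        Indexed by sgRNA id with columns ``gene``, ``is_nontargeting``,
        ``is_mirna``.
    samples : DataFrame
        Indexed by sample id with columns ``condition`` (one of T0 /
        untreated / treated) and ``replicate``.
    size_factors : Series or None
        Per-sample scalars set by :func:`normalize_depth`; None while raw.
    """

    counts: pd.DataFrame
    guides: pd.DataFrame
    samples: pd.DataFrame
    size_factors: pd.Series | None = None
    log: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            dupes = self.counts.index[self.counts.index.duplicated()].tolist()
            raise ValueError(f"duplicate sgRNA ids: {dupes[:5]}")
        if self.samples.index.has_duplicates:
            raise ValueError("duplicate sample ids in sample sheet")
        if not self.counts.index.equals(self.guides.index):
            raise ValueError("counts and guide annotation indices differ")
        missing = set(self.counts.columns) - set(self.samples.index)
        if missing:
            raise ValueError(f"samples missing from sample sheet: {sorted(missing)}")
        bad = set(self.samples["condition"]) - set(CONDITIONS)
        if bad:
            raise ValueError(
                f"unknown condition labels {sorted(bad)}; expected one of {CONDITIONS}"
            )
        absent = [c for c in CONDITIONS if c not in set(self.samples["condition"])]
        if absent:
            warnings.warn(
                f"sample sheet has no {'/'.join(absent)} samples; the corresponding "
                "contrasts will be unavailable",
                stacklevel=2,
            )

    @property
    def n_guides(self) -> int:
        return self.counts.shape[0]

    def condition_samples(self, condition: str) -> list[str]:
        ids = self.samples.index[self.samples["condition"] == condition]
        return [s for s in self.counts.columns if s in set(ids)]

    @property
    def nontargeting_ids(self) -> pd.Index:
        return self.guides.index[self.guides["is_nontargeting"]]


def read_counts(counts_path, sample_sheet_path, annotation_path=None) -> CountMatrix:
    """Read a tab-delimited count table and a CSV sample sheet.

    The count table is MAGeCK-style: header ``sgRNA<TAB>gene<TAB><samples...>``
    with an optional ``is_mirna`` column. Non-targeting guides are flagged
    by ``gene == "NONTARGETING"``. An optional annotation TSV
    (``sgRNA, gene[, is_mirna]``) overrides the in-table annotation.
    """
    df = pd.read_csv(counts_path, sep="\t")
    if df.columns[0] != "sgRNA" or df.columns[1] != "gene":
        raise ValueError(
            f"{counts_path}: expected header starting 'sgRNA<TAB>gene', got "
            f"{list(df.columns[:2])}"
        )
    df = df.set_index("sgRNA")
    mirna = df.pop("is_mirna").astype(bool) if "is_mirna" in df.columns else None
    genes = df.pop("gene")
    counts = df
    for col in counts.columns:
        vals = pd.to_numeric(counts[col], errors="raise")
        neg = vals.index[vals < 0]
        if len(neg):
            raise ValueError(
                f"{counts_path}: negative count at sgRNA={neg[0]!r}, sample={col!r}"
            )
        if not np.allclose(vals, np.round(vals)):
            raise ValueError(f"{counts_path}: non-integer counts in sample {col!r}")
    counts = counts.astype(np.int64)

    if annotation_path is not None:
        ann = pd.read_csv(annotation_path, sep="\t").set_index("sgRNA")
        genes = ann["gene"].reindex(counts.index)
        if genes.isna().any():
            missing = counts.index[genes.isna()][0]
            raise ValueError(f"{annotation_path}: no annotation for sgRNA {missing!r}")
        if "is_mirna" in ann.columns:
            mirna = ann["is_mirna"].reindex(counts.index).fillna(False).astype(bool)
    guides = pd.DataFrame({
        "gene": genes,
        "is_nontargeting": genes == NONTARGETING,
        "is_mirna": mirna if mirna is not None else False,
    }, index=counts.index)

    samples = pd.read_csv(sample_sheet_path)
    required = {"sample_id", "condition", "replicate"}
    if not required.issubset(samples.columns):
        raise ValueError(
            f"{sample_sheet_path}: sample sheet must have columns {sorted(required)}"
        )
    samples = samples.set_index("sample_id")
    return CountMatrix(counts=counts, guides=guides, samples=samples)


def write_counts(cm: CountMatrix, counts_path, sample_sheet_path=None) -> None:
    """Write the count table (and optionally the sample sheet) back to disk."""
    out = cm.counts.copy()
    out.insert(0, "gene", cm.guides["gene"])
    out.index.name = "sgRNA"
    out.to_csv(counts_path, sep="\t")
    if sample_sheet_path is not None:
        cm.samples.reset_index().to_csv(sample_sheet_path, index=False)


def filter_guides(cm: CountMatrix, trim_frac: float = 0.05,
                  bottleneck_frac: float = 0.2) -> CountMatrix:
    """Remove the lowest-count guides library-wide plus miRNA guides.

    Guides are ranked by total raw count summed across all samples;
    ``floor(trim_frac * n)`` lowest guides are removed, ties at the cutoff
    broken by lexicographic sgRNA id (smaller id removed first). All
    ``is_mirna`` guides are removed afterwards. Aborts if filtering would
    remove every guide of more than ``bottleneck_frac`` of genes.
    """
    totals = cm.counts.sum(axis=1)
    order = pd.DataFrame({"total": totals, "sgrna": totals.index}).sort_values(
        ["total", "sgrna"], kind="mergesort"
    )
    n_trim = int(np.floor(trim_frac * cm.n_guides))
    trimmed = pd.Index(order.index[:n_trim])
    mirna = cm.guides.index[cm.guides["is_mirna"]]
    removed = trimmed.union(mirna)
    keep = cm.counts.index.difference(removed)

    genes_before = set(cm.guides.loc[~cm.guides["is_nontargeting"], "gene"])
    kept_guides = cm.guides.loc[keep]
    genes_after = set(kept_guides.loc[~kept_guides["is_nontargeting"], "gene"])
    lost = genes_before - genes_after
    if genes_before and len(lost) > bottleneck_frac * len(genes_before):
        raise ValueError(
            f"filtering would remove all guides of {len(lost)}/{len(genes_before)} "
            f"genes (> {bottleneck_frac:.0%}); aborting (population bottleneck?)"
        )
    keep = cm.counts.index[cm.counts.index.isin(keep)]  # preserve original order
    logger.info(
        "filter_guides: removed %d low-count and %d miRNA guides (%d genes lost)",
        n_trim, len(mirna), len(lost),
    )
    log = dict(cm.log)
    log["filter_guides"] = {
        "n_trimmed_low_count": n_trim,
        "trimmed_ids": trimmed.tolist(),
        "n_mirna_removed": int(len(mirna)),
        "genes_lost": sorted(lost),
    }
    return CountMatrix(counts=cm.counts.loc[keep], guides=cm.guides.loc[keep],
                       samples=cm.samples, size_factors=None, log=log)


def normalize_depth(cm: CountMatrix, min_nontargeting: int = 50) -> CountMatrix:
    """Normalize sequencing depth against the non-targeting guides.

    Median-of-ratios restricted to non-targeting guides with no zero count
    in any sample: for sample j, ``sf_j = median_i(count_ij / geomean_i)``.
    Factors are rescaled to geometric mean 1 (making the operation
    idempotent) and counts are divided by them.
    """
    nt = cm.nontargeting_ids
    if len(nt) < min_nontargeting:
        raise ValueError(
            f"need >= {min_nontargeting} non-targeting guides, found {len(nt)}"
        )
    ntc = cm.counts.loc[nt].astype(float)
    zero_sample = ntc.columns[(ntc <= 0).all(axis=0)]
    if len(zero_sample):
        raise ValueError(
            f"all non-targeting guides are zero in sample(s) {zero_sample.tolist()}"
        )
    usable = ntc.loc[(ntc > 0).all(axis=1)]
    if usable.empty:
        raise ValueError("no non-targeting guide is zero-free across samples")
    geomean = np.exp(np.log(usable).mean(axis=1))
    sf = usable.div(geomean, axis=0).median(axis=0)
    sf /= np.exp(np.log(sf).mean())  # geometric mean 1 -> idempotent
    normalized = cm.counts.astype(float).div(sf, axis=1)
    log = dict(cm.log)
    log["normalize_depth"] = {"n_nontargeting_used": int(usable.shape[0])}
    return CountMatrix(counts=normalized, guides=cm.guides, samples=cm.samples,
                       size_factors=sf, log=log)


def compute_l2fc(cm: CountMatrix, contrast: tuple[str, str] = ("treated", "untreated"),
                 pseudocount: float = 1.0) -> pd.Series:
    """Guide-level log2 fold change between two conditions.

    ``L2FC = log2((mean normalized numerator + pc) / (mean normalized
    denominator + pc))`` with replicate means taken per condition.
    """
    num_cond, den_cond = contrast
    num = cm.condition_samples(num_cond)
    den = cm.condition_samples(den_cond)
    if not num or not den:
        raise ValueError(f"contrast {contrast} needs samples in both conditions")
    if cm.size_factors is None:
        warnings.warn("computing L2FC on unnormalized counts", stacklevel=2)
    mean_num = cm.counts[num].mean(axis=1)
    mean_den = cm.counts[den].mean(axis=1)
    l2fc = np.log2((mean_num + pseudocount) / (mean_den + pseudocount))
    l2fc.name = f"l2fc_{num_cond}_vs_{den_cond}"
    return l2fc


def collapse_genes(guide_l2fc: pd.Series, genes: pd.Series) -> pd.DataFrame:
    """Collapse guide-level L2FC to genes by the arithmetic mean.

    Returns a frame indexed by gene with columns ``l2fc`` and ``n_guides``.
    Genes with zero surviving guides simply do not appear (logged upstream).
    """
    df = pd.DataFrame({"l2fc": guide_l2fc, "gene": genes.reindex(guide_l2fc.index)})
    if df["gene"].isna().any():
        raise ValueError("guide without gene label in collapse_genes")
    out = df.groupby("gene", sort=True)["l2fc"].agg(["mean", "size"])
    out.columns = ["l2fc", "n_guides"]
    return out


def make_pseudo_genes(cm_or_ids, guides_per_gene: int = 6, seed: int = 0) -> pd.Series:
    """Randomly group non-targeting guides into library-sized pseudo-genes.

    Deterministic under ``seed``; ``floor(n_nt / guides_per_gene)``
    pseudo-genes are formed and leftover guides are discarded. Returns a
    Series mapping sgRNA id to pseudo-gene label.
    """
    if isinstance(cm_or_ids, CountMatrix):
        ids = cm_or_ids.nontargeting_ids
    else:
        ids = pd.Index(cm_or_ids)
    n_nt = len(ids)
    if n_nt < guides_per_gene:
        raise ValueError(
            f"need >= {guides_per_gene} non-targeting guides, found {n_nt}"
        )
    rng = np.random.default_rng(seed)
    shuffled = np.array(sorted(ids))
    rng.shuffle(shuffled)
    n_genes = n_nt // guides_per_gene
    used = shuffled[: n_genes * guides_per_gene]
    labels = [f"NT_PSEUDO_{i // guides_per_gene + 1:04d}" for i in range(len(used))]
    return pd.Series(labels, index=pd.Index(used, name="sgRNA"), name="pseudo_gene")


def score_vs_null(gene_values: pd.Series, null_values, n_boot: int = 10_000,
                  seed: int = 0) -> pd.DataFrame:
    """Score gene values against an empirical (pseudo-gene) null.

    z-scores use the null mean and sd; the two-sided empiric p-value is the
    fraction of ``n_boot`` resamples (with replacement) of the null whose
    |z| meets or exceeds the gene's |z|, floored at ``1/n_boot``; q-values
    are Benjamini-Hochberg adjusted across the scored genes.
    """
    null_values = np.asarray(null_values, dtype=float)
    if null_values.size < 30:
        raise ValueError(f"need >= 30 null values, got {null_values.size}")
    mu = float(np.mean(null_values))
    sd = float(np.std(null_values, ddof=1))
    if sd == 0:
        raise ValueError("null distribution has zero spread; cannot z-score")
    z = (gene_values - mu) / sd
    rng = np.random.default_rng(seed)
    boot = rng.choice(null_values, size=n_boot, replace=True)
    boot_abs = np.sort(np.abs((boot - mu) / sd))
    # p = fraction of resampled |z| >= |z_gene|
    n_ge = n_boot - np.searchsorted(boot_abs, np.abs(z.to_numpy()), side="left")
    p = np.maximum(n_ge / n_boot, 1.0 / n_boot)
    fdr = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame({"z": z, "p_empiric": p, "fdr": fdr}, index=gene_values.index)


@dataclass(frozen=True)
class ConcordanceResult:
    odds_ratio: float
    p_value: float
    haldane_corrected: bool


def concordance_test(table) -> ConcordanceResult:
    """One-tailed Fisher's exact test of a 2x2 concordance table.

    The odds ratio is ``(a d) / (b c)``, with a Haldane correction of 0.5
    added to every cell when any cell is zero (flagged). The p-value is the
    hypergeometric one-tailed (enrichment) probability.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0) or not np.allclose(t, np.round(t)):
        raise ValueError("table must be a 2x2 array of non-negative integers")
    corrected = bool(np.any(t == 0))
    tc = t + 0.5 if corrected else t
    odds = float(tc[0, 0] * tc[1, 1] / (tc[0, 1] * tc[1, 0]))
    p = float(stats.fisher_exact(t.astype(int), alternative="greater")[1])
    return ConcordanceResult(odds_ratio=odds, p_value=p, haldane_corrected=corrected)
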