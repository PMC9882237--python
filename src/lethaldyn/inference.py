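"""Death-rate inference from chemo-genetic screen fold changes.

A conventional screen score (treated-vs-untreated L2FC) is the sequencing
analogue of relative viability: it conflates a clone's proliferation rate
with its drug-induced death rate, so slow-growing knockouts of
death-sensitizing genes (DNA repair genes are the canonical case) can
score as "resistant". Because death under the assayed conditions occurs
only after cells stop proliferating, the biphasic forward model maps each
(growth rate, death rate) pair to a unique L2FC pair, and the map is
strictly monotone in the death rate at fixed growth rate. That
monotonicity lets the death rate be read back off the L2FC manifold:

1. the clone's growth rate comes from the untreated-vs-T0 contrast,
   ``g_hat = g_wt + l2fc_unt_t0 / T_unt0``;
2. the death rate is the root of
   ``predict_l2fc(g_hat, d) = l2fc_tx_unt``, found by bisection;
3. the gene is scored on ``L2DR = log2(d_hat / d_wt)`` against the
   pseudo-gene null.

Genes whose observed L2FC lies off the achievable manifold for their
growth rate are clipped to the boundary and flagged, not dropped.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from sklearn.base import BaseEstimator

from . import screen as _screen
from .popdyn import AssayDesign, predict_l2fc

__all__ = [
    "AssayDesign",
    "PhaseDiagram",
    "infer_growth_rate",
    "build_phase_diagram",
    "infer_death_rate",
    "classify_error_type",
    "DeathRateAnalyzer",
    "analyze_screen",
]

#: growth-rate floor (doublings/h) applied when the implied rate is <= 0
G_FLOOR = 1e-5


@dataclass(frozen=True)
class PhaseDiagram:
    """Predicted treated/untreated L2FC over a (growth, death) rate grid."""

    g_grid: np.ndarray
    d_grid: np.ndarray
    l2fc_surface: np.ndarray  # shape (len(d_grid), len(g_grid))
    design: AssayDesign

    def achievable_range(self, j: int) -> tuple[float, float]:
        """(min, max) predicted L2FC along the death axis for column j."""
        col = self.l2fc_surface[:, j]
        return float(col.min()), float(col.max())

    def to_frame(self) -> pd.DataFrame:
        """Tidy frame with columns g, d, l2fc_tx_unt."""
        gg, dd = np.meshgrid(self.g_grid, self.d_grid)
        return pd.DataFrame({
            "g": gg.ravel(), "d": dd.ravel(), "l2fc_tx_unt": self.l2fc_surface.ravel(),
        })


def infer_growth_rate(l2fc_unt_t0, design: AssayDesign, floor: float = G_FLOOR):
    """Infer clone growth rate(s) from the untreated-vs-T0 contrast.

    Non-targeting-anchored L2FC means the wild-type reference maps to 0, so
    ``g_hat = g_wt + l2fc_unt_t0 / T_unt0``. Rates implied <= 0 are floored
    at a small positive epsilon and flagged.

    Returns ``(g_hat, floored)`` arrays (scalars in, scalars out).
    """
    l2fc = np.asarray(l2fc_unt_t0, dtype=float)
    g_hat = design.g_wt + l2fc / design.T_unt0
    floored = g_hat <= 0
    g_hat = np.where(floored, floor, g_hat)
    if g_hat.ndim == 0:
        return float(g_hat), bool(floored)
    return g_hat, floored


def build_phase_diagram(design: AssayDesign, g_grid=None, d_grid=None) -> PhaseDiagram:
    """Fill the forward-model L2FC surface and assert its monotonicity.

    Defaults span 0.1x to 2x the wild-type rates. The surface must be
    non-increasing along the death axis at every growth rate (strictly
    decreasing until any killable-fraction plateau) and strictly
    decreasing along the growth axis; inversion relies on this.
    """
    if g_grid is None:
        g_grid = np.linspace(0.1, 2.0, 40) * design.g_wt
    if d_grid is None:
        d_grid = np.linspace(0.1, 2.0, 40) * design.d_wt
    g_grid = np.asarray(g_grid, dtype=float)
    d_grid = np.asarray(d_grid, dtype=float)
    if np.any(np.diff(g_grid) <= 0) or np.any(np.diff(d_grid) <= 0):
        raise ValueError("grids must be strictly increasing")
    gg, dd = np.meshgrid(g_grid, d_grid)
    surface, _ = predict_l2fc(gg, dd, design)
    if np.any(np.diff(surface, axis=0) > 1e-12):
        raise ValueError("forward model not monotone along the death axis")
    if np.any(np.diff(surface, axis=1) >= 0):
        raise ValueError("forward model not strictly decreasing along the growth axis")
    return PhaseDiagram(g_grid=g_grid, d_grid=d_grid, l2fc_surface=surface,
                        design=design)


def infer_death_rate(l2fc_tx_unt: float, g_hat: float, design: AssayDesign,
                     d_max: float | None = None, xtol: float = 1e-12):
    """Invert the forward model to a death rate for one clone.

    Solves ``predict_l2fc(g_hat, d, design) = l2fc_tx_unt`` for ``d`` by
    bisection on ``[0, d_max]`` (``d_max`` defaults to ``10 * d_wt``). If
    the observed L2FC lies outside the range achievable at this growth
    rate — above the zero-death ceiling or below the floor reached at
    ``d_max`` (for ``lfp < 1``, the non-killable plateau bounds the floor)
    — the death rate is clipped to that boundary and flagged.

    Returns ``(d_hat, on_manifold)``.
    """
    if g_hat <= 0:
        raise ValueError(f"g_hat must be > 0, got {g_hat}")
    if d_max is None:
        d_max = 10.0 * design.d_wt if design.d_wt > 0 else 0.1
    top, _ = predict_l2fc(g_hat, 0.0, design)
    bottom, _ = predict_l2fc(g_hat, d_max, design)
    if l2fc_tx_unt >= top:
        return 0.0, bool(abs(l2fc_tx_unt - top) <= 1e-9)
    if l2fc_tx_unt <= bottom:
        return float(d_max), bool(abs(l2fc_tx_unt - bottom) <= 1e-9)

    def f(d: float) -> float:
        return predict_l2fc(g_hat, d, design)[0] - l2fc_tx_unt

    d_hat = brentq(f, 0.0, d_max, xtol=xtol)
    return float(d_hat), True


_SIGNS = {-1: "sensitizing", 0: "null", 1: "resistance"}


def classify_error_type(l2fc_tx_unt, l2dr, tau_fc: float = 0.25,
                        tau_dr: float = 0.25):
    """Classify how a conventional L2FC call errs relative to the death rate.

    The conventional call is ``sign(-l2fc)`` where ``|l2fc| > tau_fc``
    (depletion = sensitizing), else null; the rate-based call is
    ``sign(l2dr)`` where ``|l2dr| > tau_dr``, else null.

    - Type I: conventional non-null, rate-based null (false positive)
    - Type II: conventional null, rate-based non-null (false negative)
    - Type III: both non-null with opposite signs (inverted inference)
    - none: otherwise (concordant, or both null)
    """
    l2fc = np.asarray(l2fc_tx_unt, dtype=float)
    l2dr_ = np.asarray(l2dr, dtype=float)
    conv = np.where(np.abs(l2fc) > tau_fc, np.sign(-l2fc), 0.0)
    true = np.where(np.abs(l2dr_) > tau_dr, np.sign(l2dr_), 0.0)
    out = np.full(np.broadcast(conv, true).shape, "none", dtype=object)
    out[(conv != 0) & (true == 0)] = "I"
    out[(conv == 0) & (true != 0)] = "II"
    out[(conv != 0) & (true != 0) & (conv != true)] = "III"
    if out.ndim == 0:
        return str(out[()])
    return out.astype(str)


class DeathRateAnalyzer(BaseEstimator):
    """End-to-end death-rate analysis of a pooled screen count matrix.

    ``fit`` runs: guide filtering -> non-targeting depth normalization ->
    guide-level L2FC for both contrasts -> gene-level collapse ->
    non-targeting pseudo-genes -> growth- and death-rate inference ->
    L2DR scoring against the pseudo-gene null -> error-type classification.

    Parameters
    ----------
    design : AssayDesign or None
        Contrast durations and wild-type reference rates (default design
        if None).
    trim_frac, pseudocount, guides_per_gene, n_boot, seed : see the
        corresponding :mod:`lethaldyn.screen` functions.
    tau_fc, tau_dr : float
        Minimal absolute effects for the error-type taxonomy.
    d_max_factor : float
        Upper bisection bound as a multiple of ``d_wt``.
    l2dr_floor_ratio : float
        ``d_hat`` is floored at ``d_wt * l2dr_floor_ratio`` when computing
        L2DR so clones clipped to the zero-death boundary stay finite
        (flagged in ``d_floored``).

    Attributes
    ----------
    results_ : DataFrame
        Per targeting gene: ``n_guides, l2fc_tx_unt, l2fc_unt_t0, g_hat,
        g_floored, d_hat, d_floored, on_manifold, l2dr, z, p_empiric, fdr,
        z_growth, error_class``.
    null_ : DataFrame
        The same rate columns for the non-targeting pseudo-genes.
    phase_diagram_ : PhaseDiagram
        Built at fit time; its construction asserts forward-model
        monotonicity before any inversion.
    manifest_ : dict
        Parameters, seed and documented methodological deviations.
    """

    def __init__(self, design: AssayDesign | None = None, trim_frac: float = 0.05,
                 pseudocount: float = 1.0, guides_per_gene: int = 6,
                 n_boot: int = 10_000, seed: int = 0, tau_fc: float = 0.25,
                 tau_dr: float = 0.25, d_max_factor: float = 10.0,
                 l2dr_floor_ratio: float = 0.01):
        self.design = design
        self.trim_frac = trim_frac
        self.pseudocount = pseudocount
        self.guides_per_gene = guides_per_gene
        self.n_boot = n_boot
        self.seed = seed
        self.tau_fc = tau_fc
        self.tau_dr = tau_dr
        self.d_max_factor = d_max_factor
        self.l2dr_floor_ratio = l2dr_floor_ratio

    def _rates_table(self, gene_tx: pd.DataFrame, gene_unt: pd.DataFrame,
                     design: AssayDesign) -> pd.DataFrame:
        df = pd.DataFrame({
            "n_guides": gene_tx["n_guides"],
            "l2fc_tx_unt": gene_tx["l2fc"],
            "l2fc_unt_t0": gene_unt["l2fc"].reindex(gene_tx.index),
        })
        g_hat, g_floored = infer_growth_rate(df["l2fc_unt_t0"].to_numpy(), design)
        d_max = self.d_max_factor * design.d_wt
        d_hat = np.empty(len(df))
        on_manifold = np.empty(len(df), dtype=bool)
        for i, (l2fc, g) in enumerate(zip(df["l2fc_tx_unt"].to_numpy(), g_hat)):
            d_hat[i], on_manifold[i] = infer_death_rate(l2fc, g, design, d_max=d_max)
        d_floor = design.d_wt * self.l2dr_floor_ratio
        d_floored = d_hat < d_floor
        l2dr = np.log2(np.maximum(d_hat, d_floor) / design.d_wt)
        df["g_hat"] = g_hat
        df["g_floored"] = g_floored
        df["d_hat"] = d_hat
        df["d_floored"] = d_floored
        df["on_manifold"] = on_manifold
        df["l2dr"] = l2dr
        return df

    def fit(self, cm: "_screen.CountMatrix", y=None):
        design = self.design if self.design is not None else AssayDesign()
        self.phase_diagram_ = build_phase_diagram(design)

        filtered = _screen.filter_guides(cm, trim_frac=self.trim_frac)
        normalized = _screen.normalize_depth(filtered)
        l2fc_tx = _screen.compute_l2fc(normalized, ("treated", "untreated"),
                                       pseudocount=self.pseudocount)
        l2fc_unt = _screen.compute_l2fc(normalized, ("untreated", "T0"),
                                        pseudocount=self.pseudocount)

        guides = normalized.guides
        targeting = ~guides["is_nontargeting"]
        gene_tx = _screen.collapse_genes(l2fc_tx[targeting], guides["gene"])
        gene_unt = _screen.collapse_genes(l2fc_unt[targeting], guides["gene"])
        pseudo = _screen.make_pseudo_genes(normalized,
                                           guides_per_gene=self.guides_per_gene,
                                           seed=self.seed)
        null_tx = _screen.collapse_genes(l2fc_tx[pseudo.index], pseudo)
        null_unt = _screen.collapse_genes(l2fc_unt[pseudo.index], pseudo)

        results = self._rates_table(gene_tx, gene_unt, design)
        null = self._rates_table(null_tx, null_unt, design)
        scores = _screen.score_vs_null(results["l2dr"], null["l2dr"].to_numpy(),
                                       n_boot=self.n_boot, seed=self.seed)
        g_scores = _screen.score_vs_null(results["g_hat"], null["g_hat"].to_numpy(),
                                         n_boot=self.n_boot, seed=self.seed)
        results = results.join(scores)
        results["z_growth"] = g_scores["z"]
        results["error_class"] = classify_error_type(
            results["l2fc_tx_unt"].to_numpy(), results["l2dr"].to_numpy(),
            tau_fc=self.tau_fc, tau_dr=self.tau_dr,
        )
        results.index.name = "gene"
        null.index.name = "gene"
        self.results_ = results
        self.null_ = null
        self.manifest_ = {
            "params": {k: v for k, v in self.get_params().items() if k != "design"},
            "design": asdict(design),
            "seed": self.seed,
            "filter_log": {
                k: {kk: vv for kk, vv in v.items() if kk != "trimmed_ids"}
                for k, v in normalized.log.items()
            },
            "deviations": [
                "L2FC is the pseudocounted log-ratio of replicate-mean "
                "non-targeting-normalized counts (no dispersion shrinkage); "
                "the empiric pseudo-gene null absorbs the slightly wider spread.",
            ],
        }
        return self

    def save(self, out_dir) -> None:
        """Write gene_death_rates.tsv, phase_diagram.tsv and the run manifest."""
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.results_.reset_index().to_csv(out / "gene_death_rates.tsv",
                                           sep="\t", index=False)
        self.null_.reset_index().to_csv(out / "pseudo_gene_null.tsv",
                                        sep="\t", index=False)
        self.phase_diagram_.to_frame().to_csv(out / "phase_diagram.tsv",
                                              sep="\t", index=False)
        (out / "run_manifest.json").write_text(json.dumps(self.manifest_, indent=2))


def analyze_screen(cm: "_screen.CountMatrix", design: AssayDesign | None = None,
                   **options) -> pd.DataFrame:
    """Run the full death-rate pipeline; returns the per-gene result table."""
    return DeathRateAnalyzer(design=design, **options).fit(cm).results_
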