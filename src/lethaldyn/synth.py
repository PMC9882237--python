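"""Ground-truthed synthetic inputs for every other module.

Emulates the design of a GeCKOv2-style chemo-genetic screen — 6 guides per
gene plus a bank of non-targeting guides, 300-500x coverage, three
replicates of T0 / untreated / treated arms, a treated arm reaching about
half-lethal fraction by assay end — and FLICK-style plate-reader
timecourses. Every sampled quantity is deterministic under the config
seed, and gene-level ground truth (growth and death multipliers) is
recorded so that recovery by the inference pipeline can be benchmarked.

The generator only runs the forward population model; it shares no code
with the inversion step, which keeps recovery tests non-circular.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .popdyn import AssayDesign, BiphasicParams, population_live, simulate_population
from .screen import NONTARGETING, CountMatrix, concordance_test

__all__ = [
    "SyntheticScreenConfig",
    "generate_truth",
    "simulate_screen_counts",
    "generate_plate_timecourse",
    "PlateSet",
    "benchmark_recovery",
]

# log2-scale (mean, sd) of the growth and death multipliers per gene class.
# Repair-like knockouts carry the strong growth defect that makes them the
# canonical inverted-inference (Type III) case; pure death modulators leave
# growth untouched.
DEFAULT_EFFECTS: dict[str, dict[str, tuple[float, float]]] = {
    "essential": {"g": (-1.0, 0.3), "d": (0.0, 0.0)},
    "repair_like": {"g": (-1.2, 0.2), "d": (1.0, 0.25)},
    "death_sensitizer": {"g": (0.0, 0.0), "d": (1.0, 0.25)},
    "death_suppressor": {"g": (0.0, 0.0), "d": (-1.0, 0.25)},
}


@dataclass(frozen=True)
class SyntheticScreenConfig:
    """Design parameters of a synthetic pooled screen.

    Defaults are test scale (1,000 genes); the full library scale
    (19,050 genes x 6 guides + 1,000 non-targeting) is supported by
    raising ``n_genes``.
    """

    n_genes: int = 1000
    guides_per_gene: int = 6
    n_nontargeting: int = 1000
    coverage: float = 400.0            # reads per guide per sample
    frac_essential: float = 0.10
    frac_repair: float = 0.05          # repair-like: g down, d up
    frac_death_up: float = 0.05        # death sensitizers: d up only
    frac_death_down: float = 0.05      # death suppressors: d down only
    effect_sizes: dict = field(default_factory=lambda: DEFAULT_EFFECTS)
    guide_jitter_sd: float = 0.10      # log2 sd of guide-level efficacy jitter
    baseline_log2_sd: float = 0.50     # library representation spread
    dispersion: float = 0.01           # gamma-Poisson overdispersion
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        fracs = (self.frac_essential, self.frac_repair, self.frac_death_up,
                 self.frac_death_down)
        if any(f < 0 for f in fracs) or sum(fracs) > 1:
            raise ValueError(f"class fractions must be >= 0 and sum <= 1, got {fracs}")
        if self.coverage <= 0:
            raise ValueError("coverage must be > 0")
        if self.n_nontargeting < self.guides_per_gene:
            raise ValueError("need at least one pseudo-gene worth of NT guides")


def _class_counts(config: SyntheticScreenConfig) -> dict[str, int]:
    n = config.n_genes
    counts = {
        "essential": int(round(config.frac_essential * n)),
        "repair_like": int(round(config.frac_repair * n)),
        "death_sensitizer": int(round(config.frac_death_up * n)),
        "death_suppressor": int(round(config.frac_death_down * n)),
    }
    counts["neutral"] = n - sum(counts.values())
    return counts


def generate_truth(config: SyntheticScreenConfig) -> pd.DataFrame:
    """Draw the gene-level truth table.

    Class sizes are deterministic (rounded fractions of ``n_genes``); which
    genes land in which class, and their multipliers, are sampled under the
    config seed. Multipliers are lognormal on the log2 scale with the
    per-class (mean, sd) from ``config.effect_sizes``; neutral genes have
    both multipliers exactly 1.

    Returns a frame indexed by gene with columns ``gene_class``, ``g_mult``,
    ``d_mult``.
    """
    rng = np.random.default_rng(config.seed)
    genes = np.array([f"GENE{i:05d}" for i in range(config.n_genes)])
    order = rng.permutation(config.n_genes)
    counts = _class_counts(config)
    labels = np.full(config.n_genes, "neutral", dtype=object)
    start = 0
    for cls in ("essential", "repair_like", "death_sensitizer", "death_suppressor"):
        labels[order[start:start + counts[cls]]] = cls
        start += counts[cls]
    g_mult = np.ones(config.n_genes)
    d_mult = np.ones(config.n_genes)
    for cls, spec in config.effect_sizes.items():
        idx = np.flatnonzero(labels == cls)
        if not len(idx):
            continue
        gm, gs = spec["g"]
        dm, ds = spec["d"]
        g_mult[idx] = np.exp2(rng.normal(gm, gs, size=len(idx))) if gs or gm else 1.0
        d_mult[idx] = np.exp2(rng.normal(dm, ds, size=len(idx))) if ds or dm else 1.0
    return pd.DataFrame(
        {"gene_class": labels, "g_mult": g_mult, "d_mult": d_mult},
        index=pd.Index(genes, name="gene"),
    )


def _guide_truth(truth: pd.DataFrame, config: SyntheticScreenConfig,
                 rng: np.random.Generator) -> pd.DataFrame:
    """Expand gene truth to guides with log2-scale efficacy jitter."""
    k = config.guides_per_gene
    genes = np.repeat(truth.index.to_numpy(), k)
    ids = np.array([f"sg_{g}_{i % k + 1}" for i, g in enumerate(genes)])
    jit = config.guide_jitter_sd
    g_mult = np.repeat(truth["g_mult"].to_numpy(), k)
    d_mult = np.repeat(truth["d_mult"].to_numpy(), k)
    neutral = np.repeat((truth["gene_class"] == "neutral").to_numpy(), k)
    if jit > 0:
        g_j = np.exp2(rng.normal(0.0, jit, size=len(ids)))
        d_j = np.exp2(rng.normal(0.0, jit, size=len(ids)))
        # neutral genes stay exactly neutral; jitter models efficacy of real edits
        g_mult = np.where(neutral, g_mult, g_mult * g_j)
        d_mult = np.where(neutral, d_mult, d_mult * d_j)
    nt_ids = np.array([f"sg_NT_{i + 1:05d}" for i in range(config.n_nontargeting)])
    guide = pd.DataFrame({
        "gene": np.concatenate([genes, np.full(config.n_nontargeting, NONTARGETING)]),
        "g_mult": np.concatenate([g_mult, np.ones(config.n_nontargeting)]),
        "d_mult": np.concatenate([d_mult, np.ones(config.n_nontargeting)]),
    }, index=pd.Index(np.concatenate([ids, nt_ids]), name="sgRNA"))
    return guide


def simulate_screen_counts(truth: pd.DataFrame, design: AssayDesign,
                           config: SyntheticScreenConfig
                           ) -> tuple[CountMatrix, dict]:
    """Simulate an overdispersed count matrix from the gene-level truth.

    Expected clone abundances at T0, untreated (``T_unt0``) and treated
    (``T_tx``) follow the biphasic forward model per guide; reads are then
    sampled per replicate as gamma-Poisson counts at depth
    ``coverage x n_guides``. Returns the count matrix and a manifest
    recording seed, config and design.
    """
    rng = np.random.default_rng(config.seed)
    guide = _guide_truth(truth, config, rng)
    g = design.g_wt * guide["g_mult"].to_numpy()
    d = design.d_wt * guide["d_mult"].to_numpy()
    baseline = np.exp2(rng.normal(0.0, config.baseline_log2_sd, size=len(guide)))

    abund = {
        "T0": baseline,
        "untreated": baseline * np.exp2(g * design.T_unt0),
        "treated": baseline * population_live(
            g, d, design.T_tx, design.t_arrest, design.lfp, arrest=True
        ),
    }
    if abund["treated"].sum() < 1e-9 * abund["T0"].sum():
        raise ValueError(
            "treated arm went effectively extinct; use milder death effects"
        )

    depth = config.coverage * len(guide)
    counts = {}
    for cond in ("T0", "untreated", "treated"):
        p = abund[cond] / abund[cond].sum()
        mu = depth * p
        for rep in range(1, config.n_replicates + 1):
            if config.dispersion > 0:
                lam = rng.gamma(shape=1.0 / config.dispersion,
                                scale=mu * config.dispersion)
            else:
                lam = mu
            counts[f"{cond}_r{rep}"] = rng.poisson(lam)
    counts_df = pd.DataFrame(counts, index=guide.index)

    guides = pd.DataFrame({
        "gene": guide["gene"],
        "is_nontargeting": guide["gene"] == NONTARGETING,
        "is_mirna": False,
    }, index=guide.index)
    samples = pd.DataFrame({
        "sample_id": list(counts_df.columns),
        "condition": [c.rsplit("_r", 1)[0] for c in counts_df.columns],
        "replicate": [int(c.rsplit("_r", 1)[1]) for c in counts_df.columns],
    }).set_index("sample_id")
    cm = CountMatrix(counts=counts_df, guides=guides, samples=samples)
    manifest = {
        "seed": config.seed,
        "config": {k: v for k, v in asdict(config).items() if k != "effect_sizes"},
        "effect_sizes": config.effect_sizes,
        "design": asdict(design),
        "depth_per_sample": depth,
    }
    return cm, manifest


@dataclass(frozen=True)
class PlateSet:
    """Synthetic FLICK-style plate output.

    ``plate`` holds the kinetic dead-cell signal (well, dose_um, time_h,
    dead_signal); ``totals`` the lysed-plate totals per well; ``truth`` the
    noise-free live/dead counts and lethal fraction per well and time.
    """

    plate: pd.DataFrame
    totals: pd.DataFrame
    truth: pd.DataFrame


def generate_plate_timecourse(params: BiphasicParams, noise_cv: float = 0.05,
                              n_timepoints: int = 13, seed: int = 0,
                              t_end: float = 96.0, n0: float = 2000.0,
                              signal_per_cell: float = 1.0,
                              dose_um: float = 31.6,
                              n_wells: int = 3) -> PlateSet:
    """Generate treated + untreated viability timecourses with known truth.

    Fluorescence is ``signal_per_cell x cell count`` with multiplicative
    lognormal noise of the stated CV; untreated companion wells (dose 0)
    grow exponentially without death. Doubling ``signal_per_cell`` rescales
    every signal by a common gain and leaves all derived LF/FV/GR values
    unchanged.
    """
    if n_timepoints < 6:
        raise ValueError("need at least 6 timepoints")
    rng = np.random.default_rng(seed)
    times = np.linspace(0.0, t_end, n_timepoints)
    sigma = np.sqrt(np.log1p(noise_cv**2)) if noise_cv > 0 else 0.0

    def noisy(x):
        x = np.asarray(x, dtype=float)
        if sigma == 0:
            return x.copy()
        return x * rng.lognormal(-0.5 * sigma**2, sigma, size=x.shape)

    plate_rows, totals_rows, truth_rows = [], [], []
    arms = [("tx", dose_um, params)]
    arms += [("unt", 0.0, BiphasicParams(tau_c=params.tau_c, t_arrest=params.t_arrest,
                                         d=0.0, lfp=params.lfp,
                                         arrest_enabled=False, death_enabled=False))]
    for arm, dose, p in arms:
        for w in range(1, n_wells + 1):
            well = f"{arm}_{w}"
            traj = simulate_population(p, times, n0=n0)
            dead_sig = noisy(traj.dead * signal_per_cell)
            total = (traj.live + traj.dead) * signal_per_cell
            plate_rows.append(pd.DataFrame({
                "well": well, "dose_um": dose, "time_h": times,
                "dead_signal": dead_sig,
            }))
            totals_rows.append({
                "well": well,
                "total_signal_t0": float(noisy(total[0])),
                "total_signal_end": float(noisy(total[-1])),
            })
            with np.errstate(invalid="ignore"):
                lf = traj.dead / (traj.live + traj.dead)
            truth_rows.append(pd.DataFrame({
                "well": well, "time_h": times, "live": traj.live,
                "dead": traj.dead, "lf": lf,
            }))
    return PlateSet(
        plate=pd.concat(plate_rows, ignore_index=True),
        totals=pd.DataFrame(totals_rows),
        truth=pd.concat(truth_rows, ignore_index=True),
    )


def _direction(mult, tol: float = 1e-9):
    l2 = np.log2(np.asarray(mult, dtype=float))
    return np.where(np.abs(l2) > tol, np.sign(l2), 0.0)


def benchmark_recovery(truth: pd.DataFrame, results: pd.DataFrame,
                       tau_fc: float = 0.25, tau_dr: float = 0.25) -> dict:
    """Benchmark inferred death rates against the generator's truth table.

    Reports Spearman correlation between true and inferred death-rate
    multipliers among death-modulating genes, per-class sign concordance of
    the rate-based (L2DR) and conventional (sign of -L2FC) calls, Fisher
    odds ratios of each method's direction calls versus truth, and the
    census of conventional-analysis error types.
    """
    df = truth.join(results, how="inner")
    if df.empty:
        raise ValueError("no overlapping genes between truth and results")
    true_dir = _direction(df["d_mult"])
    modulating = df[true_dir != 0]
    mod_dir = _direction(modulating["d_mult"])

    rho = float(stats.spearmanr(modulating["d_mult"], modulating["d_hat"]).statistic) \
        if len(modulating) >= 3 else float("nan")

    concordance = {}
    for cls, sub in df.groupby("gene_class"):
        sub_dir = _direction(sub["d_mult"])
        if np.all(sub_dir == 0):
            continue
        sel = sub[sub_dir != 0]
        sdir = _direction(sel["d_mult"])
        concordance[cls] = {
            "n": int(len(sel)),
            "l2dr_sign_concordance": float(np.mean(np.sign(sel["l2dr"]) == sdir)),
            "l2fc_sign_concordance": float(np.mean(np.sign(-sel["l2fc_tx_unt"]) == sdir)),
        }

    def _fisher(call_sign):
        called = modulating[(call_sign != 0)]
        cdir = call_sign[call_sign != 0]
        tdir = mod_dir[call_sign != 0]
        table = np.array([
            [np.sum((cdir > 0) & (tdir > 0)), np.sum((cdir > 0) & (tdir < 0))],
            [np.sum((cdir < 0) & (tdir > 0)), np.sum((cdir < 0) & (tdir < 0))],
        ])
        res = concordance_test(table)
        return {"n_called": int(len(called)), "odds_ratio": res.odds_ratio,
                "p_value": res.p_value, "table": table.tolist()}

    l2dr_call = np.where(np.abs(modulating["l2dr"]) > tau_dr,
                         np.sign(modulating["l2dr"]), 0.0)
    l2fc_call = np.where(np.abs(modulating["l2fc_tx_unt"]) > tau_fc,
                         np.sign(-modulating["l2fc_tx_unt"]), 0.0)
    census = df["error_class"].value_counts().to_dict() \
        if "error_class" in df.columns else {}
    return {
        "n_genes": int(len(df)),
        "n_death_modulating": int(len(modulating)),
        "spearman_d_mult": rho,
        "sign_concordance_by_class": concordance,
        "fisher_l2dr": _fisher(l2dr_call),
        "fisher_l2fc": _fisher(l2fc_call),
        "error_type_census": {str(k): int(v) for k, v in census.items()},
    }
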