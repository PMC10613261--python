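"""Synthetic two-population GWAS generator and fine-mapping metrics.

The generator emulates the benchmark conditions used to validate the
method: a target locus embedded in a larger background region, AR(1)
block LD with population-specific decay (weak LD in population 1, strong
LD in population 2, so that genetic diversity is informative), bivariate
normal polygenic effects on every SNP, a small number of shared sparse
causal SNPs with population-specific effect sizes, marginal-regression
summary statistics, and an optional principal-component-like confounder
that inflates LD score regression intercepts above one.

Default generative values: per-SNP polygenic covariance
``[[0.005, 0.004], [0.004, 0.005]] / 500`` (per-SNP heritability 1e-5,
cross-population genetic correlation 0.8) and per-causal-SNP effect
variance ``0.25/500 = 5e-4`` independently per population (a 50-fold
per-SNP heritability enrichment over the polygenic background).  The
default locus/background sizes (p = 200 SNPs in the locus, 5,000
background SNPs for the LDSC stage) are working-scale choices; the
per-SNP generative quantities above do not depend on them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigurationError, InputError
from .io import AlignedDataset, LDMatrix, SummaryStats
from .ldsc import LDScores, PolygenicParams, estimate_polygenic_params

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# configuration and truth
# ---------------------------------------------------------------------------


@dataclass
class ScenarioConfig:
    """Generative settings for one simulation scenario.

    ``h2_polygenic``/``ref_locus_size`` define the per-SNP polygenic
    covariance ``omega = h2_polygenic / ref_locus_size`` (with correlation
    ``gencor``); ``sigma2_causal`` is the per-causal-SNP effect variance per
    population.  ``confounder_var`` gives the per-population variance of
    the structure confounder (0 disables it; scenario 2 uses (0.05, 0.2)
    and switches the polygenic background off).
    """

    p: int = 200                       # SNPs in the fine-mapped locus
    p_genome: int = 5000               # total SNPs incl. background (LDSC stage)
    K_true: int = 3
    n: tuple[int, int] = (20000, 20000)
    h2_polygenic: float = 0.005
    gencor: float = 0.8
    ref_locus_size: int = 500
    sigma2_causal: float = 0.25 / 500
    confounder_var: tuple[float, float] = (0.0, 0.0)
    block_size: int = 50
    rho: tuple[float, float] = (0.25, 0.95)
    # background blocks cycle through these decays so LD scores vary along
    # the genome (real LD is heterogeneous; a single decay would leave the
    # LDSC slope unidentifiable)
    background_rho: tuple[tuple[float, ...], tuple[float, ...]] = (
        (0.0, 0.3, 0.5, 0.7), (0.3, 0.6, 0.8, 0.95))
    effect_df: float | None = None     # scaled-t causal effects (robustness)
    # SD of the per-SNP loadings of the structure confounder.  Loadings are
    # iid and independent of local LD (ancestry allele-frequency
    # differences, the driver of stratification, are not LD-structured),
    # which is what makes the confounder inflate the LDSC intercept rather
    # than the slope.  Expected intercept: c ~ 1 + n * v * sd^2.
    struct_loading_sd: float = 0.02
    use_candidates: bool = True        # causal SNPs drawn from the diversity filter
    seed: int | None = None
    n_reps: int = 50

    def __post_init__(self) -> None:
        if self.p_genome < self.p:
            raise ConfigurationError("p_genome must be >= p")
        if self.sigma2_causal < 0 or self.h2_polygenic < 0:
            raise ConfigurationError("variances must be >= 0")
        if abs(self.gencor) > 1:
            raise ConfigurationError("genetic correlation must be in [-1, 1]")
        if any(abs(r) >= 1 for r in self.rho):
            raise ConfigurationError("AR(1) decay must satisfy |rho| < 1")

    @property
    def omega_per_snp(self) -> np.ndarray:
        """2x2 per-SNP polygenic covariance implied by the heritability spec."""
        w = self.h2_polygenic / self.ref_locus_size
        w12 = self.gencor * w
        return np.array([[w, w12], [w12, w]])

    @classmethod
    def scenario1(cls, **kw) -> "ScenarioConfig":
        """Polygenic background + sparse causal SNPs, no confounding."""
        return cls(**kw)

    @classmethod
    def scenario2(cls, **kw) -> "ScenarioConfig":
        """Structure confounder, no polygenic background."""
        kw.setdefault("confounder_var", (0.05, 0.2))
        kw.setdefault("h2_polygenic", 0.0)
        return cls(**kw)


@dataclass
class SimulationTruth:
    """Ground truth of one replicate."""

    causal_idx: np.ndarray             # indices into the locus SNPs
    beta: np.ndarray                   # (K_true, 2)
    phi: np.ndarray                    # (p_genome, 2)
    confounder_var: tuple[float, float]
    struct_loading: np.ndarray | None = None   # (p_genome, 2) confounder loadings


# ---------------------------------------------------------------------------
# LD construction
# ---------------------------------------------------------------------------


def _ar1_block(size: int, rho: float) -> np.ndarray:
    idx = np.arange(size)
    return rho ** np.abs(idx[:, None] - idx[None, :])


def make_ld(p: int, block_size: int, rho: float,
            snp_prefix: str = "rs") -> LDMatrix:
    """Block-diagonal AR(1) LD: r_jl = rho^|j-l| within blocks of
    ``block_size`` SNPs, zero across blocks.  PSD by construction."""
    R = np.zeros((p, p))
    for start in range(0, p, block_size):
        stop = min(start + block_size, p)
        R[start:stop, start:stop] = _ar1_block(stop - start, rho)
    ids = np.array([f"{snp_prefix}{j:06d}" for j in range(p)], dtype=object)
    return LDMatrix(ids, R)


class LDBlocks:
    """Block-diagonal LD over many SNPs, stored per block.

    Keeps the genome-wide LDSC stage cheap: Cholesky factors, LD scores and
    summary-statistic draws are all per-block operations.
    """

    def __init__(self, blocks: list[np.ndarray], snp_id: np.ndarray) -> None:
        self.blocks = blocks
        self.snp_id = np.asarray(snp_id, dtype=object)
        self.p = int(sum(b.shape[0] for b in blocks))
        if self.p != self.snp_id.shape[0]:
            raise InputError("SNP ids do not match total block size")
        self._chol: list[np.ndarray] | None = None
        self._bounds = np.concatenate([[0], np.cumsum([b.shape[0] for b in blocks])])

    @classmethod
    def ar1(cls, p: int, block_size: int, rho: float,
            snp_prefix: str = "rs") -> "LDBlocks":
        blocks = []
        for start in range(0, p, block_size):
            blocks.append(_ar1_block(min(block_size, p - start), rho))
        ids = np.array([f"{snp_prefix}{j:06d}" for j in range(p)], dtype=object)
        return cls(blocks, ids)

    @property
    def chol(self) -> list[np.ndarray]:
        if self._chol is None:
            self._chol = [np.linalg.cholesky(b + 1e-10 * np.eye(len(b)))
                          for b in self.blocks]
        return self._chol

    def matvec(self, v: np.ndarray) -> np.ndarray:
        out = np.empty_like(v)
        for b, block in enumerate(self.blocks):
            sl = slice(self._bounds[b], self._bounds[b + 1])
            out[sl] = block @ v[sl]
        return out

    def ld_scores(self) -> np.ndarray:
        return np.concatenate([(b ** 2).sum(axis=1) for b in self.blocks])

    def cross_scores(self, other: "LDBlocks") -> np.ndarray:
        if self.p != other.p:
            raise InputError("mismatched LD block structures")
        return np.concatenate([(a * b).sum(axis=1)
                               for a, b in zip(self.blocks, other.blocks)])

    def dense_head(self, p: int) -> LDMatrix:
        """Dense LD of the first ``p`` SNPs (the fine-mapped locus)."""
        R = np.zeros((p, p))
        for b, block in enumerate(self.blocks):
            lo, hi = self._bounds[b], self._bounds[b + 1]
            if lo >= p:
                break
            hi = min(hi, p)
            R[lo:hi, lo:hi] = block[:hi - lo, :hi - lo]
        np.fill_diagonal(R, 1.0)
        return LDMatrix(self.snp_id[:p], R)

    def draw_block(self, b: int, n: int, rng: np.random.Generator,
                   u: np.ndarray | None = None,
                   f: np.ndarray | None = None) -> np.ndarray:
        """Standardized genotypes of block ``b`` for ``n`` samples.

        When a structure axis ``u`` (per-sample, variance ~1) and per-SNP
        loadings ``f`` are given, ``u * f_j`` is added to SNP j before
        standardization (an ancestry-like frequency shift).  Re-calling
        with a generator in the same state reproduces the block exactly,
        which lets large genotype matrices be streamed in two passes.
        """
        L = self.chol[b]
        X = rng.standard_normal((n, L.shape[0])) @ L.T
        if u is not None and f is not None:
            sl = slice(self._bounds[b], self._bounds[b + 1])
            X += np.outer(u, f[sl])
        X -= X.mean(axis=0)
        X /= X.std(axis=0)
        return X

    def draw_genotypes(self, n: int, rng: np.random.Generator,
                       u: np.ndarray | None = None,
                       f: np.ndarray | None = None) -> np.ndarray:
        """n x p standardized (mean-0, variance-1 columns) genotypes with
        this LD, drawn as multivariate normal."""
        X = np.empty((n, self.p))
        for b in range(len(self.blocks)):
            sl = slice(self._bounds[b], self._bounds[b + 1])
            X[:, sl] = self.draw_block(b, n, rng, u=u, f=f)
        return X

    def draw_allele_counts(self, n: int, rng: np.random.Generator,
                           maf: float = 0.3) -> np.ndarray:
        """Discrete 0/1/2 allele counts for realism spot checks.

        Two latent haplotype layers with this block LD are thresholded at
        the minor-allele frequency and summed; the threshold attenuates the
        latent correlations (roughly the tetrachoric-to-phi reduction), so
        the realized LD is a damped version of the AR(1) target.  The
        likelihood depends only on second moments, which is why the main
        generation path stays Gaussian.
        """
        from scipy.stats import norm
        q = norm.ppf(1.0 - maf)
        counts = np.zeros((n, self.p), dtype=np.int8)
        for _ in range(2):
            counts += (self.draw_genotypes(n, rng) > q).astype(np.int8)
        return counts


def candidate_causal_snps(ld_weak: LDMatrix, ld_strong: LDMatrix,
                          strong_r: float = 0.9, min_strong: int = 3,
                          weak_r: float = 0.6, max_weak: int = 2) -> np.ndarray:
    """Leverage-of-diversity candidates: SNPs in high LD (|r| > strong_r)
    with at least ``min_strong`` others in the strong-LD population while
    weakly correlated (|r| > weak_r with fewer than ``max_weak`` others) in
    the weak-LD population."""
    a_strong = np.abs(ld_strong.R) > strong_r
    a_weak = np.abs(ld_weak.R) > weak_r
    n_strong = a_strong.sum(axis=1) - 1
    n_weak = a_weak.sum(axis=1) - 1
    return np.nonzero((n_strong >= min_strong) & (n_weak < max_weak))[0]


# ---------------------------------------------------------------------------
# effects and summary statistics
# ---------------------------------------------------------------------------


def _draw_bivariate(rng: np.random.Generator, cov: np.ndarray,
                    size: int) -> np.ndarray:
    L = np.linalg.cholesky(cov + 1e-18 * np.eye(2))
    return rng.standard_normal((size, 2)) @ L.T


def simulate_effects(cfg: ScenarioConfig, rng: np.random.Generator,
                     candidates: np.ndarray | None = None) -> SimulationTruth:
    """Draw polygenic and sparse causal effects for one replicate.

    Polygenic effects are bivariate normal with the per-SNP covariance of
    the config on all ``p_genome`` SNPs (zero when the polygenic
    heritability is zero).  ``K_true`` causal indices are sampled from the
    candidate set (or any locus SNP), greedily spaced so no two causal SNPs
    fall in the same LD block; their effects are drawn independently per
    population with variance ``sigma2_causal`` (or from a variance-matched
    scaled t when ``effect_df`` is set).
    """
    if cfg.h2_polygenic > 0:
        phi = _draw_bivariate(rng, cfg.omega_per_snp, cfg.p_genome)
    else:
        phi = np.zeros((cfg.p_genome, 2))

    pool = np.arange(cfg.p) if candidates is None or len(candidates) == 0 \
        else np.asarray(candidates)
    if cfg.K_true > len(pool):
        raise ConfigurationError(
            f"K_true = {cfg.K_true} exceeds {len(pool)} candidate SNPs")
    if cfg.K_true > 0:
        shuffled = rng.permutation(pool)
        chosen: list[int] = []
        for j in shuffled:
            if all(abs(j - c) >= cfg.block_size or j // cfg.block_size != c // cfg.block_size
                   for c in chosen):
                chosen.append(int(j))
            if len(chosen) == cfg.K_true:
                break
        if len(chosen) < cfg.K_true:  # fall back to unconstrained sampling
            chosen = rng.choice(pool, size=cfg.K_true, replace=False).tolist()
        causal_idx = np.array(sorted(chosen))
        if cfg.effect_df is not None:
            scale = np.sqrt(cfg.sigma2_causal * (cfg.effect_df - 2) / cfg.effect_df)
            beta = scale * rng.standard_t(cfg.effect_df, size=(cfg.K_true, 2))
        else:
            beta = np.sqrt(cfg.sigma2_causal) * rng.standard_normal((cfg.K_true, 2))
    else:
        causal_idx = np.array([], dtype=int)
        beta = np.zeros((0, 2))
    struct = None
    if any(v > 0 for v in cfg.confounder_var):
        struct = rng.normal(scale=cfg.struct_loading_sd, size=(cfg.p_genome, 2))
    return SimulationTruth(causal_idx=causal_idx, beta=beta, phi=phi,
                           confounder_var=cfg.confounder_var,
                           struct_loading=struct)


def _as_blocks(ld) -> LDBlocks:
    if isinstance(ld, LDBlocks):
        return ld
    if isinstance(ld, LDMatrix):
        return LDBlocks([ld.R], ld.snp_id)
    raise InputError("expected LDMatrix or LDBlocks")


def _effect_vector(truth: SimulationTruth, t: int, p_total: int) -> np.ndarray:
    b = np.zeros(p_total)
    if len(truth.causal_idx):
        b[truth.causal_idx] = truth.beta[:, t]
    return b


def simulate_sumstats(truth: SimulationTruth, lds, cfg: ScenarioConfig,
                      rng: np.random.Generator,
                      mode: str = "summary") -> list[SummaryStats]:
    """Generate per-population marginal summary statistics.

    summary mode
        Draw ``bhat_t ~ N(R_t (b_t + phi_t) + delta_t, S_t R_t S_t)`` with
        ``s_tj = 1/sqrt(n_t)``.  The confounder enters as the mean shift
        ``delta_tj = sqrt(v_t) * f_tj`` where ``f_t`` are the per-SNP
        structure loadings: a fixed confounder of variance ``v_t`` biases
        the marginal effect of SNP j by its correlation with the structure
        axis.  LDSC then sees an intercept of roughly
        ``1 + n_t * v_t * struct_loading_sd^2``.
    individual mode
        Draw standardized genotypes with the population's LD (plus the
        ancestry-like frequency shifts ``u_i * f_tj`` when the confounder
        is on), build the phenotype from polygenic + causal effects plus
        the structure axis rescaled to variance ``v_t``, and run per-SNP
        marginal regressions.  Genotypes are streamed per LD block in two
        passes (phenotype construction, then regression) so the full
        ``n x p`` matrix is never materialized.
    """
    blocks = [_as_blocks(ld) for ld in lds]
    p_total = blocks[0].p
    if truth.phi.shape[0] < p_total:
        raise InputError("truth covers fewer SNPs than the LD structure")
    out: list[SummaryStats] = []
    for t, ldb in enumerate(blocks):
        n_t = cfg.n[t]
        v_t = truth.confounder_var[t]
        f_t = None
        if v_t > 0:
            if truth.struct_loading is None:
                raise ConfigurationError(
                    "confounder variance > 0 but truth has no structure loadings")
            f_t = truth.struct_loading[:p_total, t]
        g = _effect_vector(truth, t, p_total) + truth.phi[:p_total, t]
        if mode == "summary":
            mean = ldb.matvec(g)
            if f_t is not None:
                mean = mean + np.sqrt(v_t) * f_t
            s = 1.0 / np.sqrt(n_t)
            noise = np.empty(p_total)
            for b, L in enumerate(ldb.chol):
                sl = slice(ldb._bounds[b], ldb._bounds[b + 1])
                noise[sl] = L @ rng.standard_normal(L.shape[0])
            bhat = mean + s * noise
            se = np.full(p_total, s)
        elif mode == "individual":
            h2_poly = cfg.h2_polygenic / cfg.ref_locus_size * p_total
            h2_causal = cfg.sigma2_causal * cfg.K_true
            var_e = 1.0 - h2_poly - h2_causal - v_t
            if var_e <= 0:
                raise ConfigurationError(
                    "heritability + confounder variance >= 1; no residual left")
            u = rng.standard_normal(n_t) if f_t is not None else None
            n_blocks = len(ldb.blocks)
            block_seeds = rng.integers(0, 2 ** 63, size=n_blocks)
            # pass 1: accumulate the genetic part of the phenotype
            y = np.zeros(n_t)
            for b in range(n_blocks):
                sl = slice(ldb._bounds[b], ldb._bounds[b + 1])
                Xb = ldb.draw_block(b, n_t, np.random.default_rng(block_seeds[b]),
                                    u=u, f=f_t)
                y += Xb @ g[sl]
            if u is not None:
                pc = (u - u.mean()) / u.std() * np.sqrt(v_t)
                y = y + pc
            y = y + rng.normal(scale=np.sqrt(var_e), size=n_t)
            # pass 2: per-SNP marginal regressions, regenerating each block
            # from its recorded seed (columns are standardized, so x'x = n)
            yty = float(y @ y)
            bhat = np.empty(p_total)
            se = np.empty(p_total)
            for b in range(n_blocks):
                sl = slice(ldb._bounds[b], ldb._bounds[b + 1])
                Xb = ldb.draw_block(b, n_t, np.random.default_rng(block_seeds[b]),
                                    u=u, f=f_t)
                bhat[sl] = Xb.T @ y / n_t
                sse = yty - bhat[sl] ** 2 * n_t
                se[sl] = np.sqrt(sse / (n_t * n_t))
        else:
            raise ConfigurationError(f"unknown generation mode '{mode}'")
        out.append(SummaryStats(
            snp_id=ldb.snp_id,
            allele_effect=np.full(p_total, "A"),
            allele_other=np.full(p_total, "G"),
            bhat=bhat, se=se, n=np.full(p_total, float(n_t)),
        ))
    return out


# ---------------------------------------------------------------------------
# end-to-end replicate
# ---------------------------------------------------------------------------


@dataclass
class SimulatedReplicate:
    """Everything one replicate produces: genome-wide stats for the LDSC
    stage, the harmonizable locus dataset, LD scores and the truth."""

    cfg: ScenarioConfig
    truth: SimulationTruth
    genome_stats: list[SummaryStats]
    genome_ld: list[LDBlocks]
    locus: AlignedDataset
    scores: list[LDScores]
    scores_cross: LDScores

    def estimate_params(self, n_blocks: int = 200,
                        clamp_c: bool = True) -> PolygenicParams:
        """Stage-1 LDSC estimation from the genome-wide statistics."""
        z1 = self.genome_stats[0].zscores
        z2 = self.genome_stats[1].zscores
        return estimate_polygenic_params(
            z1, z2, self.scores[0], self.scores[1], self.scores_cross,
            n1=float(np.median(self.genome_stats[0].n)),
            n2=float(np.median(self.genome_stats[1].n)),
            n_blocks=n_blocks, clamp_c=clamp_c)


def make_genome_ld(cfg: ScenarioConfig) -> list[LDBlocks]:
    """Per-population block LD for the whole region.

    The fine-mapped locus (first ``p`` SNPs) uses the population's headline
    decay ``rho``; background blocks cycle through ``background_rho`` so the
    genome-wide LD scores span a range (needed for the LDSC slope).
    """
    out = []
    for t in range(2):
        blocks: list[np.ndarray] = []
        pos, bg_i = 0, 0
        while pos < cfg.p_genome:
            size = min(cfg.block_size, cfg.p_genome - pos)
            if pos < cfg.p:
                rho = cfg.rho[t]
            else:
                grid = cfg.background_rho[t]
                rho = grid[bg_i % len(grid)]
                bg_i += 1
            blocks.append(_ar1_block(size, rho))
            pos += size
        ids = np.array([f"rs{j:06d}" for j in range(cfg.p_genome)], dtype=object)
        out.append(LDBlocks(blocks, ids))
    return out


def simulate_replicate(cfg: ScenarioConfig, rng: np.random.Generator,
                       mode: str = "summary",
                       genome_ld: list[LDBlocks] | None = None,
                       ) -> SimulatedReplicate:
    """One full replicate: LD, effects, genome-wide stats, locus dataset."""
    if genome_ld is None:
        genome_ld = make_genome_ld(cfg)
    locus_ld = [ldb.dense_head(cfg.p) for ldb in genome_ld]
    candidates = None
    if cfg.use_candidates:
        candidates = candidate_causal_snps(locus_ld[0], locus_ld[1])
        if len(candidates) < cfg.K_true:
            log.warning("only %d diversity candidates; falling back to all "
                        "locus SNPs", len(candidates))
            candidates = None
    truth = simulate_effects(cfg, rng, candidates=candidates)
    genome_stats = simulate_sumstats(truth, genome_ld, cfg, rng, mode=mode)
    locus_stats = [st.subset(np.arange(cfg.p)) for st in genome_stats]
    locus = AlignedDataset(stats=locus_stats, lds=locus_ld)
    scores = [LDScores(ldb.snp_id, ldb.ld_scores()) for ldb in genome_ld]
    scores_cross = LDScores(genome_ld[0].snp_id, genome_ld[0].ld_scores(),
                            genome_ld[0].cross_scores(genome_ld[1]))
    return SimulatedReplicate(cfg=cfg, truth=truth, genome_stats=genome_stats,
                              genome_ld=genome_ld, locus=locus,
                              scores=scores, scores_cross=scores_cross)


# ---------------------------------------------------------------------------
# evaluation metrics
# ---------------------------------------------------------------------------


def _roc_points(labels: np.ndarray, scores: np.ndarray
                ) -> tuple[np.ndarray, np.ndarray]:
    """ROC curve points (FPR, TPR) over descending score thresholds, with
    tied scores grouped."""
    order = np.argsort(-scores, kind="stable")
    labels = labels[order]
    scores = scores[order]
    distinct = np.nonzero(np.diff(scores))[0]
    cuts = np.r_[distinct, labels.size - 1]
    tps = np.cumsum(labels)[cuts]
    fps = 1 + cuts - tps
    P = labels.sum()
    N = labels.size - P
    tpr = np.r_[0.0, tps / max(P, 1)]
    fpr = np.r_[0.0, fps / max(N, 1)]
    return fpr, tpr


def partial_auc(labels: np.ndarray, scores: np.ndarray, fpr_cap: float) -> float:
    """Trapezoidal area under the ROC curve truncated at ``fpr_cap``,
    normalized by the cap (1.0 = perfect ranking within the cap)."""
    fpr, tpr = _roc_points(np.asarray(labels, dtype=int),
                           np.asarray(scores, dtype=float))
    grid = np.unique(np.r_[fpr[fpr <= fpr_cap], fpr_cap])
    tpr_i = np.interp(grid, fpr, tpr)
    return float(np.trapezoid(tpr_i, grid) / fpr_cap)


def evaluate_finemapping(truth: SimulationTruth, pip: np.ndarray,
                         fdr_levels=(0.05, 0.1, 0.2),
                         fpr_caps=(0.1, 0.2, 0.3),
                         credible_sets=None) -> dict:
    """Score one replicate's PIP vector against the truth.

    Returns per-level selection counts (so FDR can be pooled across
    replicates), empirical FDR = 1 - TP/selected, power = TP / K_true,
    normalized pAUC per FPR cap, and kept credible-set sizes.
    """
    from .inference import global_fdr_select

    pip = np.asarray(pip, dtype=float)
    labels = np.zeros(pip.shape[0], dtype=int)
    labels[truth.causal_idx] = 1
    record: dict = {"levels": {}, "pauc": {}, "cs_sizes": None}
    for xi in fdr_levels:
        sel = global_fdr_select(pip, xi)
        tp = int(labels[sel.selected].sum())
        n_sel = sel.n_selected
        record["levels"][xi] = {
            "n_selected": n_sel,
            "n_true": tp,
            "fdr": float("nan") if n_sel == 0 else 1.0 - tp / n_sel,
            "power": float("nan") if labels.sum() == 0 else tp / int(labels.sum()),
        }
    if labels.sum() > 0 and labels.sum() < labels.size:
        for cap in fpr_caps:
            record["pauc"][cap] = partial_auc(labels, pip, cap)
    if credible_sets is not None:
        record["cs_sizes"] = [cs.size for cs in credible_sets if cs.kept]
    return record


# ---------------------------------------------------------------------------
# replicated benchmark studies (the package's standard evaluation runs)
# ---------------------------------------------------------------------------


def run_scenario1_study(seed: int, n_reps: int = 50, K: int = 5,
                        cfg: ScenarioConfig | None = None,
                        fdr_levels=(0.05, 0.1, 0.2),
                        alpha: float = 0.95,
                        purity: float = 0.1) -> dict:
    """Replicated no-confounding benchmark with the full two-step pipeline.

    Each replicate: draw effects and genome-wide summary statistics,
    estimate (Omega, c) by LDSC, fit the locus with K components, select
    SNPs by global FDR and build purity-filtered credible sets.  Selection
    counts are pooled across replicates (each locus holds at most K_true
    causal SNPs, so pooling sharpens the empirical FDR).
    """
    from .core import fit_xmap
    from .inference import extract_credible_sets, global_fdr_select

    cfg = cfg or ScenarioConfig.scenario1()
    genome_ld = make_genome_ld(cfg)
    counts = {xi: [0, 0] for xi in fdr_levels}   # xi -> [true pos, selected]
    cs_sizes: list[int] = []
    cs_hits: list[bool] = []
    max_pip_is_causal: list[bool] = []
    leading_sigma: list[np.ndarray] = []
    trailing_sigma: list[float] = []
    for child in np.random.SeedSequence(seed).spawn(n_reps):
        rng = np.random.default_rng(child)
        rep = simulate_replicate(cfg, rng, genome_ld=genome_ld)
        params = rep.estimate_params()
        fit = fit_xmap(rep.locus, K=K, params=params)
        causal = set(rep.truth.causal_idx.tolist())
        for xi in fdr_levels:
            sel = global_fdr_select(fit.pip, xi)
            counts[xi][0] += len(causal & set(sel.selected.tolist()))
            counts[xi][1] += sel.n_selected
        sets = extract_credible_sets(fit, rep.locus.lds, alpha=alpha,
                                     purity=purity)
        for cs in sets:
            if cs.kept and cs.duplicate_of is None:
                cs_sizes.append(cs.size)
                cs_hits.append(bool(causal & set(cs.indices.tolist())))
        if causal:
            max_pip_is_causal.append(
                (int(np.argmax(fit.pip)) in causal,
                 global_fdr_select(fit.pip, 0.1).n_selected > 0))
        order = np.argsort(-np.linalg.eigvalsh(fit.Sigma_hat.Sigma).sum(axis=1))
        diag = fit.Sigma_hat.Sigma[order][:, [0, 1], [0, 1]]
        leading_sigma.append(diag[:cfg.K_true])
        trailing_sigma.extend(diag[cfg.K_true:].ravel().tolist())
    fdr = {xi: (float("nan") if n == 0 else 1.0 - tp / n, n)
           for xi, (tp, n) in counts.items()}
    hit_disc = [hit for hit, disc in max_pip_is_causal if disc]
    return {
        "fdr": fdr,
        "cs_sizes": np.asarray(cs_sizes),
        "cs_hit_rate": float(np.mean(cs_hits)) if cs_hits else float("nan"),
        "max_pip_causal_rate": float(np.mean([h for h, _ in max_pip_is_causal])),
        "top_pip_precision": (float(np.mean(hit_disc)) if hit_disc
                              else float("nan")),
        "leading_sigma": np.asarray(leading_sigma),
        "trailing_sigma": np.asarray(trailing_sigma),
        "n_reps": n_reps,
    }


def run_scenario2_study(seed: int, n_reps: int = 10,
                        K: int = 5, xi: float = 0.1,
                        cfg: ScenarioConfig | None = None) -> dict:
    """Confounding benchmark: individual-mode generation with the structure
    confounder, LDSC intercept estimation, and the fit run twice per
    replicate (estimated inflation constants vs. constants forced to 1)."""
    from .core import fit_xmap
    from .inference import global_fdr_select
    from .ldsc import PolygenicParams

    cfg = cfg or ScenarioConfig.scenario2(p_genome=2500, K_true=1)
    genome_ld = make_genome_ld(cfg)
    raw_c = []
    counts = {"estimated": [0, 0], "forced": [0, 0]}
    for child in np.random.SeedSequence(seed).spawn(n_reps):
        rng = np.random.default_rng(child)
        rep = simulate_replicate(cfg, rng, mode="individual",
                                 genome_ld=genome_ld)
        raw = rep.estimate_params(clamp_c=False)
        raw_c.append(raw.c.copy())
        est = PolygenicParams(omega=raw.omega, c=np.maximum(raw.c, 1.0))
        forced = PolygenicParams(omega=raw.omega, c=np.array([1.0, 1.0]))
        causal = set(rep.truth.causal_idx.tolist())
        for name, pr in (("estimated", est), ("forced", forced)):
            fit = fit_xmap(rep.locus, K=K, params=pr)
            sel = global_fdr_select(fit.pip, xi)
            counts[name][0] += len(causal & set(sel.selected.tolist()))
            counts[name][1] += sel.n_selected
    fdr = {name: float("nan") if n == 0 else 1.0 - tp / n
           for name, (tp, n) in counts.items()}
    return {"intercepts": np.asarray(raw_c), "fdr": fdr,
            "counts": counts, "n_reps": n_reps}
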