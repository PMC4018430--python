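"""Synthetic ovary-microarray studies with planted ground truth.

The generator emulates the statistical structure of a small two-group
spawn-quality study: 8 high-quality and 8 low-quality females, ~15,000
probes of which a "fingerprint" of 233 genes carries small (< 0.2 log2-fold
between-group) expression shifts tied to a single latent quality factor.
No single fingerprint gene explains more than ~2% of phenotype variance,
but collectively the suite is strongly predictive. Residual (phenotype-
independent) co-expression is organized in planted modules driven by
per-module latent factors, so that modularity clustering and relevance
networks have recoverable structure. A genotype matrix with no phenotype
association is included as a negative control.

Raw intensities are produced by inverting the generalized-log model
(``intensity = b * 2**signal + additive background``, floored at zero) so
that variance-stabilizing normalization is genuinely exercised.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from eggprint.dataio import (
    ExpressionMatrix,
    GenotypeMatrix,
    PhenotypeTable,
    ProbeAnnotation,
)

__all__ = ["SimulationConfig", "SimulationTruth", "generate_dataset"]


@dataclass
class SimulationConfig:
    """Study-design knobs for the synthetic generator.

    Defaults mirror the reference study design: 8 + 8 samples, 15,000
    probes, a 233-gene fingerprint containing 17 duplicate probe pairs,
    23 co-expression modules, per-gene group shifts capped at 0.2 log2-fold
    units and per-gene phenotype-variance shares capped at 2%.
    """

    n_high: int = 8
    n_low: int = 8
    n_probes: int = 15000
    n_duplicate_pairs: int = 17
    n_fingerprint: int = 233
    n_modules: int = 23
    max_log2_shift: float = 0.2
    max_single_gene_share: float = 0.02
    # fraction of fingerprint genes down-regulated in low-quality ovaries
    frac_down_in_low: float = 145 / 233
    # total non-phenotype sd of a fingerprint gene (glog units) and the
    # fraction of that variance shared with its module factor; the planted
    # within-module residual correlation equals within_module_r
    fingerprint_noise_sd: float = 0.075
    within_module_r: float = 0.85
    # biological across-sample sd of non-fingerprint probes (glog units)
    background_biological_sd: float = 0.25
    # raw-scale noise model
    background_mean: float = 50.0
    background_sd: float = 10.0
    array_scale_sd: float = 0.1  # lognormal sd of per-array multiplier
    multiplicative_sd: float = 0.01  # lognormal sd applied to the true signal
    # phenotype
    high_mean: float = 67.3
    high_sd: float = 8.0
    low_mean: float = 9.0
    low_sd: float = 6.0
    phenotype_noise_sd: float = 3.0  # measurement noise on percent scale
    baseline_glog_low: float = 6.0
    baseline_glog_high: float = 12.0
    # fingerprint genes are maternal transcripts: moderately-to-highly
    # expressed, clear of the additive-noise floor
    fingerprint_glog_low: float = 9.5
    n_loci: int = 48
    alleles_per_locus: int = 4
    seed: int = 0

    def validate(self) -> None:
        if self.n_fingerprint > self.n_probes:
            raise ValueError("n_fingerprint exceeds n_probes")
        if self.max_log2_shift <= 0:
            raise ValueError("max_log2_shift must be positive")
        if self.n_fingerprint > 0:
            if self.n_duplicate_pairs > self.n_fingerprint:
                raise ValueError("duplicate pairs must fit inside the fingerprint set")
            if self.n_modules < 1 or self.n_modules > self.n_fingerprint // 5:
                raise ValueError("n_modules must allow modules of size >= 5")
            # per-gene shares of the collective signal must respect the cap
            if 1.0 / self.n_fingerprint > 4 * self.max_single_gene_share:
                raise ValueError(
                    "too few fingerprint genes for the single-gene share cap"
                )
        elif self.n_duplicate_pairs > self.n_probes:
            raise ValueError("more duplicate pairs than probes")
        if not 0 <= self.frac_down_in_low <= 1:
            raise ValueError("frac_down_in_low must be a fraction")
        if not 0 < self.within_module_r < 1:
            raise ValueError("within_module_r must be in (0, 1)")


@dataclass
class SimulationTruth:
    """Ground truth recorded by the generator for downstream validation."""

    fingerprint_gene_ids: list[str]
    effect_sizes: dict[str, float]  # signed, glog units per 1-SD latent quality
    module_of: dict[str, int]  # fingerprint gene -> planted module (1..K)
    variance_share: dict[str, float]  # intended per-gene share of phenotype variance
    latent_quality: dict[str, float]  # sample -> latent quality (% scale)
    duplicate_pairs: list[tuple[str, str]]  # (probe_a, probe_b) printed twice

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)


@dataclass
class SyntheticStudy:
    expression: ExpressionMatrix
    annotation: ProbeAnnotation
    phenotype: PhenotypeTable
    genotype: GenotypeMatrix
    truth: SimulationTruth
    # noiseless glog-scale signal, for oracle-style checks
    glog_signal: pd.DataFrame = field(repr=False, default=None)


def generate_dataset(config: SimulationConfig) -> SyntheticStudy:
    """Draw one complete synthetic study under ``config``.

    Model (glog scale), for sample i with standardized latent quality z_i:

    * fingerprint gene g:   x_gi = mu_g + beta_g * z_i + lambda * f_{m(g),i} + eps
    * other probes:         x_gi = mu_g + eps

    where f_{m,i} are per-module factors orthogonalized against z (module
    structure lives in the phenotype-independent residuals), |beta_g| is
    scaled so the high/low group shift never exceeds ``max_log2_shift`` and
    the per-gene phenotype-variance share stays below
    ``max_single_gene_share``. Raw intensities invert the glog model and add
    Gaussian background noise floored at zero.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_high + config.n_low

    # --- phenotype: latent quality on the percent scale, grouped by rule
    u_high = _truncated_normal(rng, config.high_mean, config.high_sd,
                               lo=50.5, hi=99.5, size=config.n_high)
    u_low = _truncated_normal(rng, config.low_mean, config.low_sd,
                              lo=0.5, hi=29.5, size=config.n_low)
    u = np.concatenate([u_high, u_low])
    sample_ids = [f"F{i+1:02d}" for i in range(n)]
    z = (u - u.mean()) / u.std(ddof=0)

    observed = np.clip(u + rng.normal(0.0, config.phenotype_noise_sd, n), 0.0, 100.0)
    # keep measured pct_4h consistent with group membership
    observed[: config.n_high] = np.clip(observed[: config.n_high], 50.5, 100.0)
    observed[config.n_high:] = np.clip(observed[config.n_high:], 0.0, 29.5)

    # --- fingerprint effects
    nf = config.n_fingerprint
    gene_ids = [f"UN{g+1:05d}" for g in range(config.n_probes)]
    fp_genes = gene_ids[:nf]

    dz = z[: config.n_high].mean() - z[config.n_high:].mean()
    beta_cap = config.max_log2_shift / dz
    # magnitudes sit just under the fold-shift cap: the fingerprint is a
    # suite of individually small, near-uniform effects
    mags = rng.uniform(0.85 * beta_cap, 0.95 * beta_cap, nf)
    n_down = int(round(config.frac_down_in_low * nf))
    signs = np.concatenate([np.ones(n_down), -np.ones(nf - n_down)])
    rng.shuffle(signs)
    beta = mags * signs  # positive beta: tracks quality, hence down in low

    # --- planted modules over fingerprint genes (each size >= 5)
    lam = config.fingerprint_noise_sd * np.sqrt(config.within_module_r)
    eps_sd = config.fingerprint_noise_sd * np.sqrt(1.0 - config.within_module_r)
    if nf > 0:
        module_of = _assign_modules(rng, nf, config.n_modules)
        factors = rng.normal(0.0, 1.0, (config.n_modules, n))
        # orthogonalize each factor against z and restandardize: module
        # structure lives in the phenotype-independent residuals
        factors = factors - np.outer(factors @ z / (z @ z), z)
        factors = (factors - factors.mean(axis=1, keepdims=True)) / factors.std(
            axis=1, ddof=0, keepdims=True
        )
    else:
        module_of = np.zeros(0, dtype=int)

    # --- glog-scale signal matrix
    mu = rng.uniform(config.baseline_glog_low, config.baseline_glog_high, config.n_probes)
    if nf > 0:
        mu[:nf] = rng.uniform(config.fingerprint_glog_low, config.baseline_glog_high, nf)
    signal = np.tile(mu[:, None], (1, n))
    if nf > 0:
        signal[:nf] += beta[:, None] * z[None, :]
        signal[:nf] += lam * factors[module_of - 1, :]
        signal[:nf] += rng.normal(0.0, eps_sd, (nf, n))
    signal[nf:] += rng.normal(
        0.0, config.background_biological_sd, (config.n_probes - nf, n)
    )

    # --- duplicate probes: first n_duplicate_pairs fingerprint genes get a
    # second spot measuring the same signal with independent spot noise
    probe_ids = [f"P{g+1:05d}" for g in range(config.n_probes)]
    dup_pairs: list[tuple[str, str]] = []
    dup_rows = []
    dup_probe_ids = []
    ann_rows = [
        {"probe_id": p, "gene_id": g, "duplicate_group": None}
        for p, g in zip(probe_ids, gene_ids)
    ]
    spot_sd = 0.5 * (
        config.fingerprint_noise_sd if nf > 0 else config.background_biological_sd
    )
    for k in range(config.n_duplicate_pairs):
        twin = f"P{k+1:05d}dup"
        dup_probe_ids.append(twin)
        dup_rows.append(signal[k] + rng.normal(0.0, spot_sd, n))
        group = f"dup{k+1:03d}"
        ann_rows[k]["duplicate_group"] = group
        ann_rows.append(
            {"probe_id": twin, "gene_id": gene_ids[k], "duplicate_group": group}
        )
        dup_pairs.append((probe_ids[k], twin))
    if dup_rows:
        signal = np.vstack([signal, np.array(dup_rows)])
        probe_ids = probe_ids + dup_probe_ids

    # --- raw scale: intensity = b_i * 2^signal * mult_noise + background
    array_scale = np.exp(rng.normal(0.0, config.array_scale_sd, n))
    mult = np.exp(rng.normal(0.0, config.multiplicative_sd, signal.shape))
    raw = array_scale[None, :] * (2.0**signal) * mult
    raw += rng.normal(config.background_mean, config.background_sd, signal.shape)
    raw = np.maximum(raw, 0.0)

    expression = ExpressionMatrix(
        probe_ids=probe_ids, sample_ids=sample_ids, values=raw, scale_flag="raw"
    )
    annotation = ProbeAnnotation(pd.DataFrame(ann_rows))

    pheno = _phenotype_table(rng, sample_ids, observed, config)
    geno = _null_genotypes(rng, sample_ids, config)

    beta_ss = float((beta**2).sum()) if nf > 0 else 1.0
    truth = SimulationTruth(
        fingerprint_gene_ids=list(fp_genes),
        effect_sizes={g: float(b) for g, b in zip(fp_genes, beta)},
        module_of={g: int(m) for g, m in zip(fp_genes, module_of)},
        variance_share={
            g: float(b**2 / beta_ss) for g, b in zip(fp_genes, beta)
        },
        latent_quality={s: float(v) for s, v in zip(sample_ids, u)},
        duplicate_pairs=dup_pairs,
    )
    glog_signal = pd.DataFrame(signal, index=probe_ids, columns=sample_ids)
    return SyntheticStudy(expression, annotation, pheno, geno, truth, glog_signal)


def _truncated_normal(rng, mean, sd, lo, hi, size):
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = rng.normal(mean, sd, size * 4)
        ok = draw[(draw > lo) & (draw < hi)]
        take = min(len(ok), size - filled)
        out[filled: filled + take] = ok[:take]
        filled += take
    return out


def _assign_modules(rng, n_genes: int, n_modules: int) -> np.ndarray:
    """Random module sizes, each >= 5, summing to n_genes; returns 1-based
    labels in gene order (genes of a module are contiguous)."""
    base = 5
    extra = n_genes - base * n_modules
    # multinomial split of the surplus
    add = rng.multinomial(extra, np.ones(n_modules) / n_modules)
    sizes = base + add
    labels = np.repeat(np.arange(1, n_modules + 1), sizes)
    return labels


def _phenotype_table(rng, sample_ids, pct_4h, config) -> PhenotypeTable:
    n = len(sample_ids)
    # downstream survival metrics degrade from pct_4h with extra noise
    pct_24h = np.clip(pct_4h * rng.uniform(0.75, 0.95, n), 0, 100)
    pct_hatch = np.clip(pct_24h * rng.uniform(0.7, 0.95, n), 0, 100)
    pct_5dph = np.clip(pct_hatch * rng.uniform(0.6, 0.95, n), 0, 100)
    table = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "pct_4h_viable": np.round(pct_4h, 3),
            "pct_24h_viable": np.round(pct_24h, 3),
            "pct_hatch": np.round(pct_hatch, 3),
            "pct_5dph": np.round(pct_5dph, 3),
            # broodstock matched for age/size: no group difference planted
            "body_length": np.round(rng.normal(55.0, 3.0, n), 2),
            "body_weight": np.round(rng.normal(3.6, 0.4, n), 3),
            "fecundity": np.round(rng.normal(120000, 15000, n), 0),
            "oocyte_diameter": np.round(rng.normal(900.0, 40.0, n), 1),
            "quality_label": ["high"] * config.n_high + ["low"] * config.n_low,
        }
    )
    return PhenotypeTable(table)


def _null_genotypes(rng, sample_ids, config) -> GenotypeMatrix:
    """Phenotype-independent diploid dosages at independent multi-allelic loci."""
    n = len(sample_ids)
    cols = []
    names = []
    for locus in range(config.n_loci):
        k = config.alleles_per_locus
        freqs = rng.dirichlet(np.ones(k) * 2.0)
        # draw two allele copies per sample
        a1 = rng.choice(k, size=n, p=freqs)
        a2 = rng.choice(k, size=n, p=freqs)
        dos = np.zeros((n, k), dtype=int)
        dos[np.arange(n), a1] += 1
        dos[np.arange(n), a2] += 1
        cols.append(dos)
        names.extend(f"L{locus+1:02d}:A{j+1}" for j in range(k))
    return GenotypeMatrix(
        sample_ids=list(sample_ids),
        allele_ids=names,
        dosages=np.hstack(cols),
    )
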