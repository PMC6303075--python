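"""Synthetic full-diallel generator with an explicit biallelic architecture.

Each inbred strain is a fully homozygous genome over three locus classes:

* SA loci — allelic effects of opposite sign in males and females
  (sexually antagonistic), with per-sex dominance coefficients whose
  relationship across the sexes is governed by ``dominance_mode``;
* SC loci — same-sign effects in both sexes (sexually concordant);
* load loci — recessive deleterious alleles private to one strain each,
  so they are expressed only in that strain's self family (the classic
  mechanism of inbreeding depression), optionally hitting males harder.

An F1 individual from dam i x sire j carries, at every locus, the two
parental alleles; its latent log fitness is the sum of per-locus
contributions under a one-locus dominance model (heterozygote value
2*alpha*h, h = 0.5 additive, h = 1 full dominance of allele 1), plus an
intercept, a block effect, and Gaussian noise.  Observed fitness is the
count max(0, round(exp(latent))).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .io import SEX_F, SEX_M, SEXES, DiallelDataset

DOMINANCE_MODES = ("full_reversal", "independent", "concordant", "additive")


@dataclass
class SimulationConfig:
    """Generating conditions for a synthetic diallel study.

    Defaults emulate a two-block 16x16 diallel fitness assay on the scale
    of a seed-beetle experiment: ~3 replicate assays per family x sex x
    block with mild record-level missingness (~3,000 records), a mean of
    ~40 F2 offspring per assay, strong inbreeding depression that is
    twice as severe in males, and sexually antagonistic loci with full
    sex-specific dominance reversal.
    """

    n_strains: int = 16
    n_sa_loci: int = 20
    n_sc_loci: int = 20
    n_load_loci: int = 16
    p: float = 0.5                      # allele-1 frequency across strains
    alpha_scale: float = 0.1            # half-normal scale of |effects| (log units)
    dominance_mode: str = "full_reversal"
    dominance_beta: tuple[float, float] = (6.0, 2.0)  # Beta(h) in the favoured sex
    sex_symmetric_magnitudes: bool = False  # |alpha_F| == |alpha_M| per locus
    load_scale: float = 0.5             # mean recessive-load penalty (log units)
    male_load_multiplier: float = 2.0   # >1: inbreeding hits males harder
    block_effects: tuple[float, ...] = (0.0, -0.1)
    mu0: float = float(np.log(40.0))    # baseline log fitness
    sigma_e: float = 0.3                # residual sd, log scale
    replicates: int = 3                 # per family x sex x block
    missingness: float = 0.06           # i.i.d. record drop rate
    seed: int | None = None

    def __post_init__(self):
        if self.n_strains < 2:
            raise ValueError("n_strains must be >= 2")
        if min(self.n_sa_loci, self.n_sc_loci, self.n_load_loci) < 0:
            raise ValueError("locus counts must be >= 0")
        if not 0.0 < self.p < 1.0:
            raise ValueError("allele frequency p must lie in (0,1)")
        if self.sigma_e < 0:
            raise ValueError("sigma_e must be >= 0")
        if not 0.0 <= self.missingness < 1.0:
            raise ValueError("missingness must lie in [0,1)")
        if self.dominance_mode not in DOMINANCE_MODES:
            raise ValueError(f"dominance_mode must be one of {DOMINANCE_MODES}")
        if self.replicates < 1 or len(self.block_effects) < 1:
            raise ValueError("need >= 1 replicate and >= 1 block")

    @classmethod
    def high_signal_reversal(cls, seed: int | None = None) -> "SimulationConfig":
        """Few large-effect SA loci with complete, sex-balanced dominance
        reversal and no missingness: the stated high-signal condition under
        which the cross-sex array-covariance correlation is reliably
        negative."""
        return cls(n_sa_loci=12, alpha_scale=0.30, dominance_beta=(20.0, 1.0),
                   dominance_mode="full_reversal", replicates=2,
                   sex_symmetric_magnitudes=True, missingness=0.0, seed=seed)

    @classmethod
    def concordant_control(cls, seed: int | None = None) -> "SimulationConfig":
        """Same-sign, sex-symmetric dominance at every locus (no SA loci):
        the control condition under which the cross-sex array-covariance
        correlation is positive."""
        return cls(n_sa_loci=0, n_sc_loci=30, dominance_mode="concordant",
                   sex_symmetric_magnitudes=True, replicates=4,
                   missingness=0.0, seed=seed)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("dominance_beta", "block_effects"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)


@dataclass(frozen=True)
class StrainGenome:
    """Fully homozygous genotype of one inbred strain: g[l] in {0,1}."""

    strain: int
    genotype: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "genotype",
                           np.asarray(self.genotype, dtype=np.int8))


@dataclass
class SimulationTruth:
    """The generating architecture, for judging downstream recovery.

    ``loci`` has one row per locus: kind (sa/sc/load), alpha_F, alpha_M
    (allelic effect of allele 1, log-fitness units), h_F, h_M (dominance
    of allele 1), load_strain (owner for load loci, else <NA>), delta_F,
    delta_M (recessive penalties for load loci).  ``strains`` has the
    per-strain, per-sex expected additive value and dominance index.
    """

    loci: pd.DataFrame
    strains: pd.DataFrame
    config: SimulationConfig = None

    def to_csv(self, loci_path, strains_path) -> None:
        self.loci.to_csv(loci_path, index=False)
        self.strains.to_csv(strains_path, index=False)


def _draw_dominance(rng: np.random.Generator, n: int, mode: str,
                    beta: tuple[float, float]) -> tuple[np.ndarray, np.ndarray]:
    """Per-locus dominance of allele 1 in (F, M) under the given mode."""
    a, b = beta
    if mode == "additive":
        hF = np.full(n, 0.5)
        hM = np.full(n, 0.5)
    elif mode == "concordant":
        hF = rng.beta(a, b, size=n)
        hM = hF.copy()
    elif mode == "independent":
        hF = rng.beta(a, b, size=n)
        hM = rng.beta(a, b, size=n)
    else:  # full_reversal
        hF = rng.beta(a, b, size=n)
        hM = 1.0 - hF
    return hF, hM


def simulate_strain_genomes(config: SimulationConfig,
                            rng: np.random.Generator | None = None,
                            ) -> tuple[list[StrainGenome], SimulationTruth]:
    """Draw strain genomes and the per-locus, per-sex effect table.

    SA/SC genotypes are i.i.d. Bernoulli(p) per strain; load alleles are
    private (each load locus carries allele 1 in exactly one strain,
    assigned round-robin).  Reproducible under a fixed config seed.
    """
    if rng is None:
        rng = np.random.default_rng(
            np.random.SeedSequence(config.seed).spawn(1)[0])
    n, nsa, nsc, nld = (config.n_strains, config.n_sa_loci,
                        config.n_sc_loci, config.n_load_loci)
    L = nsa + nsc + nld
    kinds = np.array(["sa"] * nsa + ["sc"] * nsc + ["load"] * nld)

    # per-sex effect magnitudes are drawn independently: antagonism (and
    # concordance) is a sign constraint, not a mirror symmetry — real
    # sex-limited architectures are asymmetric in magnitude
    mag_f = np.abs(rng.normal(0.0, config.alpha_scale, size=nsa + nsc))
    mag_m = (mag_f.copy() if config.sex_symmetric_magnitudes
             else np.abs(rng.normal(0.0, config.alpha_scale, size=nsa + nsc)))
    sign_f = rng.choice([-1.0, 1.0], size=nsa + nsc)
    alpha_F = np.zeros(L)
    alpha_M = np.zeros(L)
    alpha_F[:nsa + nsc] = sign_f * mag_f
    alpha_M[:nsa] = -sign_f[:nsa] * mag_m[:nsa]       # SA: opposite sign
    alpha_M[nsa:nsa + nsc] = sign_f[nsa:] * mag_m[nsa:]   # SC: same sign

    hF = np.full(L, 0.5)
    hM = np.full(L, 0.5)
    # SSDR semantics: h is drawn for the sex favoured by allele 1, the
    # other sex's h follows the mode.  For SC loci the mode applies with
    # "favoured sex" = F by convention (both sexes are favoured equally).
    hF_draw, hM_draw = _draw_dominance(rng, nsa + nsc, config.dominance_mode,
                                       config.dominance_beta)
    fav_is_F = alpha_F[:nsa + nsc] > 0
    hF[:nsa + nsc] = np.where(fav_is_F, hF_draw, hM_draw)
    hM[:nsa + nsc] = np.where(fav_is_F, hM_draw, hF_draw)
    if config.dominance_mode == "full_reversal" and nsa:
        hM[:nsa] = 1.0 - hF[:nsa]   # exact reversal at SA loci by contract

    geno = np.zeros((n, L), dtype=np.int8)
    if nsa + nsc:
        geno[:, :nsa + nsc] = rng.binomial(1, config.p, size=(n, nsa + nsc))
    load_owner = np.full(L, -1)
    delta_F = np.zeros(L)
    delta_M = np.zeros(L)
    for k in range(nld):
        owner = k % n
        locus = nsa + nsc + k
        load_owner[locus] = owner + 1
        geno[owner, locus] = 1
        d = rng.exponential(config.load_scale)
        delta_F[locus] = d
        delta_M[locus] = d * config.male_load_multiplier

    loci = pd.DataFrame({
        "locus": np.arange(1, L + 1), "kind": kinds,
        "alpha_F": alpha_F, "alpha_M": alpha_M, "h_F": hF, "h_M": hM,
        "load_strain": pd.array(np.where(load_owner > 0, load_owner, np.nan),
                                dtype="Int64"),
        "delta_F": delta_F, "delta_M": delta_M,
    })

    genomes = [StrainGenome(strain=i + 1, genotype=geno[i]) for i in range(n)]
    g_signed = 2.0 * geno - 1.0
    rows = []
    for s, alpha, h in ((SEX_F, alpha_F, hF), (SEX_M, alpha_M, hM)):
        add = geno @ (2.0 * alpha)             # expected homozygous value
        dom_idx = g_signed[:, :nsa + nsc] @ (2.0 * h[:nsa + nsc] - 1.0)
        for i in range(n):
            rows.append((i + 1, s, add[i], dom_idx[i] if nsa + nsc else 0.0))
    strains = pd.DataFrame(rows, columns=["strain", "sex", "additive_value",
                                          "dominance_index"])
    return genomes, SimulationTruth(loci=loci, strains=strains, config=config)


def genotypic_value(dam: StrainGenome, sire: StrainGenome, sex: str,
                    truth: SimulationTruth) -> float:
    """Latent log-fitness contribution of a dam x sire genotype in one sex.

    Per locus: 0 if both parents carry allele 0, 2*alpha if both carry
    allele 1, 2*alpha*h if heterozygous.  Load loci are fully recessive
    (h = 0): they contribute -delta(sex) only when homozygous for the
    load allele.
    """
    if sex not in SEXES:
        raise ValueError(f"sex must be one of {SEXES}")
    gi, gj = dam.genotype, sire.genotype
    if gi.shape != gj.shape:
        raise ValueError("genomes do not share a locus set")
    loci = truth.loci
    alpha = loci[f"alpha_{sex}"].to_numpy()
    h = loci[f"h_{sex}"].to_numpy()
    delta = loci[f"delta_{sex}"].to_numpy()
    is_load = (loci["kind"] == "load").to_numpy()
    hom1 = (gi == 1) & (gj == 1)
    het = gi != gj
    value = np.where(~is_load,
                     hom1 * 2.0 * alpha + het * 2.0 * alpha * h,
                     hom1 * (-delta))
    return float(value.sum())


def generate_diallel(config: SimulationConfig,
                     ) -> tuple[DiallelDataset, SimulationTruth]:
    """Simulate a full diallel dataset under the configured architecture.

    For every (dam, sire, sex, block, replicate): latent = mu0 + block
    effect + genotypic value + Normal(0, sigma_e); observed fitness =
    max(0, round(exp(latent))); records are then dropped i.i.d. at the
    missingness rate (records of strains that would vanish entirely are
    retained so the dataset stays a valid diallel).
    """
    ss = np.random.SeedSequence(config.seed).spawn(3)
    genomes, truth = simulate_strain_genomes(
        config, np.random.default_rng(ss[0]))
    rng_noise = np.random.default_rng(ss[1])
    rng_miss = np.random.default_rng(ss[2])

    n = config.n_strains
    n_blocks = len(config.block_effects)
    latent_fam = {
        (i, j, s): genotypic_value(genomes[i - 1], genomes[j - 1], s, truth)
        for i in range(1, n + 1) for j in range(1, n + 1) for s in SEXES}

    rows = []
    for i in range(1, n + 1):
        for j in range(1, n + 1):
            for s in SEXES:
                base = config.mu0 + latent_fam[(i, j, s)]
                for b in range(n_blocks):
                    lat = (base + config.block_effects[b]
                           + rng_noise.normal(0.0, config.sigma_e,
                                              size=config.replicates))
                    fit = np.maximum(0, np.round(np.exp(lat))).astype(int)
                    rows.extend((i, j, s, b + 1, f) for f in fit)
    if not rows:
        raise ValueError("configuration implies zero records")
    df = pd.DataFrame(rows, columns=["dam", "sire", "sex", "block",
                                     "fitness"])
    if config.missingness > 0:
        keep = rng_miss.random(len(df)) >= config.missingness
        # never drop a strain out of existence
        kept = df[keep]
        present = set(kept["dam"]) | set(kept["sire"])
        if len(present) < n:
            for strain in set(range(1, n + 1)) - present:
                keep[df.index[(df["dam"] == strain)][:1]] = True
            kept = df[keep]
        df = kept.reset_index(drop=True)
    return DiallelDataset(df, n_strains=n), truth
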