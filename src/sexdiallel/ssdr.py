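"""Array-covariance test for sex-specific dominance reversal (SSDR).

For each parental strain k and each sex, the array covariance sigma_P,r
(Hayman's W_r) is the covariance between k's outcross family means (r)
and the self means (P) of the partner strains, averaged over the
dam-side and sire-side arrays.  A strain whose outcross means track its
partners' self means carries alleles that are recessive to its partners';
a strain whose outcross means ignore them carries dominant alleles.
Correlating the 16 male values against the 16 female values across
strains tests whether the dominant/recessive status of strains' fixed
variation is sex-reversed (negative correlation = SSDR).

Family means are tabulated from conditional residuals of the model
y = mu + x + b3 + eps (block and symmetric-epistasis variation removed;
optionally also the SC additive BLUPs a), on the same log response used
for variance partitioning.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import SEX_F, SEX_M, DiallelDataset, FamilyMeanMatrix, \
    family_mean_table
from .reml import ModelSpec, RemlOptions, build_design, \
    conditional_residuals, fit_reml

MIN_PARTNERS = 3          # fewer usable partners per side -> unstable cov
MIN_STRAINS_FOR_TEST = 6  # cross-strain correlation below this is noise


@dataclass
class ArrayCovarianceSet:
    """Per-strain sigma_P,r and V_r for one sex.

    ``table`` columns: strain, sigma_Pr, Vr, n_dam, n_sire (usable
    partners per side).
    """

    sex: str
    table: pd.DataFrame

    @property
    def sigma_pr(self) -> np.ndarray:
        return self.table["sigma_Pr"].to_numpy()

    @property
    def vr(self) -> np.ndarray:
        return self.table["Vr"].to_numpy()

    @property
    def strains(self) -> np.ndarray:
        return self.table["strain"].to_numpy()


def array_covariance(fm: FamilyMeanMatrix, strain: int,
                     ) -> tuple[float, float]:
    """sigma_P,r and V_r of one strain from a family-mean matrix.

    sigma_P,r = 1/2 [cov(r_dam, P) + cov(r_sire, P)] where r_dam are the
    strain's dam-side outcross means z[strain, j], r_sire its sire-side
    means z[j, strain], and P the partner self means z[j, j] (j != strain,
    self pair never included).  Only partners with both the outcross mean
    and the self mean unmasked enter each side; each side needs at least
    3 usable partners.  V_r is the variance of the pooled outcross means.
    Sample statistics with n-1 denominator throughout.
    """
    n = fm.n_strains
    if not 1 <= strain <= n:
        raise ValueError(f"strain {strain} outside 1..{n}")
    k = strain - 1
    others = np.array([j for j in range(n) if j != k])
    self_ok = ~fm.mask[others, others]
    sides = []
    pooled = []
    for r_vals, r_ok in (
            (fm.values[k, others], ~fm.mask[k, others]),      # dam side
            (fm.values[others, k], ~fm.mask[others, k])):     # sire side
        use = r_ok & self_ok
        if use.sum() < MIN_PARTNERS:
            raise ValueError(
                f"strain {strain}: only {int(use.sum())} usable partners on "
                f"one side (need >= {MIN_PARTNERS})")
        r = r_vals[use]
        P = fm.values[others, others][use]
        sides.append(float(np.cov(r, P, ddof=1)[0, 1]))
        pooled.append(r_vals[r_ok])
    sigma_pr = 0.5 * (sides[0] + sides[1])
    vr = float(np.var(np.concatenate(pooled), ddof=1))
    return sigma_pr, vr


def array_covariance_set(fm: FamilyMeanMatrix) -> ArrayCovarianceSet:
    """sigma_P,r and V_r for every strain of one sex."""
    rows = []
    n = fm.n_strains
    for strain in range(1, n + 1):
        k = strain - 1
        others = np.array([j for j in range(n) if j != k])
        self_ok = ~fm.mask[others, others]
        n_dam = int((~fm.mask[k, others] & self_ok).sum())
        n_sire = int((~fm.mask[others, k] & self_ok).sum())
        spr, vr = array_covariance(fm, strain)
        rows.append((strain, spr, vr, n_dam, n_sire))
    return ArrayCovarianceSet(sex=fm.sex, table=pd.DataFrame(
        rows, columns=["strain", "sigma_Pr", "Vr", "n_dam", "n_sire"]))


def pearson_ci_fisher(r: float, n: int) -> tuple[float, float, float]:
    """95% Fisher-z confidence interval and two-sided t p-value.

    CI = tanh(atanh(r) +/- 1.96/sqrt(n-3)); p from
    t = r sqrt(n-2)/sqrt(1-r^2) on n-2 df.
    """
    if not np.isfinite(r) or abs(r) >= 1.0:
        raise ValueError("|r| must be < 1")
    if n < 4:
        raise ValueError("need n >= 4")
    z = np.arctanh(r)
    half = 1.96 / np.sqrt(n - 3)
    lo, hi = np.tanh(z - half), np.tanh(z + half)
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    p = 2.0 * float(stats.t.sf(abs(t), n - 2))
    return float(lo), float(hi), p


def _spearman_t(rho: float, n: int) -> float:
    if abs(rho) >= 1.0:
        return 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
    return 2.0 * float(stats.t.sf(abs(t), n - 2))


@dataclass
class SsdrResult:
    """Cross-sex correlation of per-strain array covariances."""

    variant: str                  # baseline / sc_additive_removed
    male: ArrayCovarianceSet
    female: ArrayCovarianceSet
    pearson_r: float
    ci_low: float
    ci_high: float
    p_pearson: float
    spearman_rho: float
    p_spearman: float
    ranks: pd.DataFrame           # strain, rank_M, rank_F
    n_strains: int

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "variant": self.variant, "pearson": self.pearson_r,
            "ci_lo": self.ci_low, "ci_hi": self.ci_high,
            "p_pearson": self.p_pearson, "spearman": self.spearman_rho,
            "p_spearman": self.p_spearman, "n": self.n_strains,
        }])

    def strain_frame(self) -> pd.DataFrame:
        m = self.male.table.assign(sex=SEX_M)
        f = self.female.table.assign(sex=SEX_F)
        return pd.concat([f, m], ignore_index=True)


def ssdr_statistics(ds: DiallelDataset, remove_sc_additive: bool = False,
                    offset: float = 1.0,
                    reml_options: RemlOptions | None = None) -> SsdrResult:
    """The full SSDR pipeline on one dataset.

    Fit y = mu + x + b3 (+ a) + eps by REML on the log response, take
    conditional residuals (fixed part and b3 BLUPs removed; a BLUPs also
    removed when ``remove_sc_additive``), tabulate per-sex family means,
    compute each strain's sigma_P,r per sex, and correlate the male
    against the female values across strains (Pearson with Fisher CI and
    t p-value; Spearman on ranks with a t-approximation p-value).
    """
    if ds.n_strains < MIN_STRAINS_FOR_TEST:
        raise ValueError(
            f"SSDR test needs >= {MIN_STRAINS_FOR_TEST} strains, got "
            f"{ds.n_strains}")
    missing_selfs = [(i, i) for i in range(1, ds.n_strains + 1)
                     if (i, i) not in ds.family_keys()]
    if missing_selfs:
        raise ValueError(
            "SSDR test requires all parental selfs; missing: "
            f"{missing_selfs} (sigma_P,r is undefined without selfs)")
    spec = ModelSpec.residualization(remove_sc_additive, offset=offset)
    fit = fit_reml(build_design(ds, spec), reml_options
                   or RemlOptions(compute_se=False))
    remove = ("x", "a", "b3") if remove_sc_additive else ("x", "b3")
    rd = conditional_residuals(fit, remove=remove)

    sets = {}
    for sex in (SEX_M, SEX_F):
        fm = family_mean_table(rd.residuals, rd.ds, sex)
        sets[sex] = array_covariance_set(fm)
    m, f = sets[SEX_M], sets[SEX_F]
    common = np.intersect1d(m.strains, f.strains)
    mv = m.table.set_index("strain").loc[common, "sigma_Pr"].to_numpy()
    fv = f.table.set_index("strain").loc[common, "sigma_Pr"].to_numpy()
    n = len(common)

    r, _ = stats.pearsonr(mv, fv)
    lo, hi, p_r = pearson_ci_fisher(float(r), n)
    rho, _ = stats.spearmanr(mv, fv)
    ranks = pd.DataFrame({"strain": common,
                          "rank_M": stats.rankdata(mv),
                          "rank_F": stats.rankdata(fv)})
    return SsdrResult(
        variant="sc_additive_removed" if remove_sc_additive else "baseline",
        male=m, female=f, pearson_r=float(r), ci_low=lo, ci_high=hi,
        p_pearson=p_r, spearman_rho=float(rho),
        p_spearman=_spearman_t(float(rho), n), ranks=ranks, n_strains=n)


def plot_ssdr(res: SsdrResult, path, ranks: bool = False) -> None:
    """Scatter of female vs male per-strain array covariances (or their
    ranks), one point per strain.  Requires matplotlib (optional)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    common = res.ranks["strain"].to_numpy()
    if ranks:
        x = res.ranks["rank_M"].to_numpy()
        y = res.ranks["rank_F"].to_numpy()
        xl, yl = "rank of sigma_P,r (males)", "rank of sigma_P,r (females)"
        note = f"Spearman rho = {res.spearman_rho:.3f}"
    else:
        x = res.male.table.set_index("strain").loc[common,
                                                   "sigma_Pr"].to_numpy()
        y = res.female.table.set_index("strain").loc[common,
                                                     "sigma_Pr"].to_numpy()
        xl, yl = "sigma_P,r (males)", "sigma_P,r (females)"
        note = (f"Pearson r = {res.pearson_r:.3f} "
                f"[{res.ci_low:.2f}, {res.ci_high:.2f}]")
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.scatter(x, y, color="k")
    for xi, yi, s in zip(x, y, common):
        ax.annotate(str(s), (xi, yi), fontsize=7,
                    textcoords="offset points", xytext=(3, 3))
    ax.set_xlabel(xl)
    ax.set_ylabel(yl)
    ax.set_title(f"{res.variant}: {note}", fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def wr_vr_diagnostic(acs: ArrayCovarianceSet) -> pd.DataFrame:
    """OLS regression of sigma_P,r on V_r across strains (one sex).

    Under pure dominance theory (no epistatic or environmental variance,
    fully inbred parents) W_r regresses on V_r with slope 1.  Returns the
    per-strain table plus slope, intercept and the regression p-value as
    frame attributes ``slope``, ``intercept``, ``p_slope``, ``r_value``.
    """
    if len(acs.table) < MIN_STRAINS_FOR_TEST:
        raise ValueError("need >= 6 strains for the Wr-Vr diagnostic")
    vr = acs.vr
    if np.allclose(vr, vr[0]):
        raise ValueError("no variance in V_r across strains")
    reg = stats.linregress(vr, acs.sigma_pr)
    out = acs.table.copy()
    out.attrs["slope"] = float(reg.slope)
    out.attrs["intercept"] = float(reg.intercept)
    out.attrs["p_slope"] = float(reg.pvalue)
    out.attrs["r_value"] = float(reg.rvalue)
    return out
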