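"""Geometric interpretation of sexed vs unsexed inheritance classes.

For an inheritance class Q, the strain BLUPs from separate male and
female models (q_M, q_F) span a bivariate coordinate system.  Rotating it
by 45 degrees yields the sexually concordant axis q_SC = (q_F + q_M)/sqrt(2)
and the sexually antagonistic axis q_SA = (q_F - q_M)/sqrt(2); no variance
is lost in the rotation.  Correlating q_SC and q_SA against the full
sexed model's unsexed (q) and sexed (S x q) BLUPs, and measuring the
angular displacement theta between q and S x q via their normalized inner
product, shows whether the sexed component describes an SA axis
(theta ~ 90 degrees).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .reml import (PAIR_TERMS, UNSEXED_TERMS, BlupVector, FitResult,
                   extract_blups)

_SQRT2 = float(np.sqrt(2.0))


def rotate_sc_sa(qF: BlupVector, qM: BlupVector,
                 ) -> tuple[BlupVector, BlupVector]:
    """Rotate variance-standardized female/male BLUP axes by 45 degrees.

    Element-wise q_SC = (q_F + q_M)/sqrt(2), q_SA = (q_F - q_M)/sqrt(2)
    (i.e. qF sin45 + qM cos45 and qF cos45 - qM sin45).  Inputs are
    standardized internally if they are not already.  The rotation
    conserves the total sum of squares.
    """
    if list(qF.labels) != list(qM.labels):
        raise ValueError("female and male BLUP vectors must share labels")
    if not qF.standardized:
        qF = qF.standardize()
    if not qM.standardized:
        qM = qM.standardize()
    sc = (qF.values + qM.values) / _SQRT2
    sa = (qF.values - qM.values) / _SQRT2
    term = qF.term
    return (BlupVector(term, "sc", list(qF.labels), sc, standardized=True),
            BlupVector(term, "sa", list(qF.labels), sa, standardized=True))


def collapse_pair_blups(pair_blups: BlupVector) -> BlupVector:
    """Collapse pair-level BLUPs to strain means.

    The value for strain k is the raw mean over the pairs containing k
    (no sign flip; for the antisymmetric reciprocal class d this is a
    reported convention, not a canonical quantity).
    """
    labels = list(pair_blups.labels)
    if not labels or not isinstance(labels[0], tuple):
        raise ValueError("collapse_pair_blups expects pair-labelled BLUPs")
    strains = sorted({s for pair in labels for s in pair})
    values = []
    for k in strains:
        sel = [v for (i, j), v in zip(labels, pair_blups.values)
               if k in (i, j)]
        if not sel:
            raise ValueError(f"strain {k} appears in no pair")
        values.append(float(np.mean(sel)))
    return BlupVector(pair_blups.term, pair_blups.model, strains,
                      np.array(values), standardized=False)


def inner_product_angle(u: BlupVector, v: BlupVector) -> float:
    """Angle in degrees between two BLUP axes.

    Both vectors are scaled to unit Euclidean norm; the inner product is
    clamped to [-1, 1] against round-off before arccos.
    """
    if list(u.labels) != list(v.labels):
        raise ValueError("vectors must share labels")
    nu = float(np.linalg.norm(u.values))
    nv = float(np.linalg.norm(v.values))
    if nu == 0 or nv == 0:
        raise ValueError("zero-norm vector has no direction")
    c = float(np.clip((u.values / nu) @ (v.values / nv), -1.0, 1.0))
    return float(np.degrees(np.arccos(c)))


@dataclass
class GeometryReport:
    """Per-class correlations and angles; excluded classes carry no
    numbers, only a reason."""

    table: pd.DataFrame  # class, r_q_qSC, p_q_qSC, r_Sq_qSA, p_Sq_qSA,
    #                      theta_deg, excluded, reason

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def row(self, cls: str) -> pd.Series:
        return self.table.set_index("class").loc[cls]


def _strain_blups(fit: FitResult, term: str) -> BlupVector:
    b = extract_blups(fit, term)
    if term in PAIR_TERMS:
        b = collapse_pair_blups(b)
    return b


def geometry_report(fit_full: FitResult, fit_M: FitResult,
                    fit_F: FitResult) -> GeometryReport:
    """Relate the full sexed model's q / S x q axes to SC / SA axes
    derived from separate male and female fits.

    For each unsexed class with valid (non-negative) components in all
    three fits: q_SC and q_SA come from rotating the standardized
    sex-specific BLUPs; they are correlated (Pearson) against the full
    model's q and S x q, and theta is the angle between q and S x q.
    Pair-level classes (b3, d) are collapsed to strain means first.
    A class with any required negative component is excluded with a
    reason.
    """
    rows = []
    for cls in UNSEXED_TERMS:
        sexed = f"S.{cls}"
        needed = [(fit_full, cls), (fit_full, sexed),
                  (fit_M, cls), (fit_F, cls)]
        negative = [f"{t}({f.model_id})" for f, t in needed
                    if t in f.varcomp and f.varcomp[t] < 0]
        absent = [t for f, t in needed if t not in f.varcomp]
        if negative or absent:
            reason = "; ".join(
                (["negative variance: " + ", ".join(negative)] if negative
                 else []) + (["absent: " + ", ".join(absent)] if absent
                             else []))
            rows.append((cls, np.nan, np.nan, np.nan, np.nan, np.nan, True,
                         reason))
            continue
        try:
            q = _strain_blups(fit_full, cls)
            sq = _strain_blups(fit_full, sexed)
            qM = _strain_blups(fit_M, cls)
            qF = _strain_blups(fit_F, cls)
            qSC, qSA = rotate_sc_sa(qF.standardize(), qM.standardize())
            r_sc, p_sc = stats.pearsonr(q.values, qSC.values)
            r_sa, p_sa = stats.pearsonr(sq.values, qSA.values)
            theta = inner_product_angle(q, sq)
        except ValueError as err:
            rows.append((cls, np.nan, np.nan, np.nan, np.nan, np.nan, True,
                         str(err)))
            continue
        rows.append((cls, float(r_sc), float(p_sc), float(r_sa), float(p_sa),
                     theta, False, ""))
    table = pd.DataFrame(rows, columns=["class", "r_q_qSC", "p_q_qSC",
                                        "r_Sq_qSA", "p_Sq_qSA", "theta_deg",
                                        "excluded", "reason"])
    return GeometryReport(table=table)
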