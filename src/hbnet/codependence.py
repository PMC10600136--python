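"""Higher-order co-dependence analyses across adjacency coefficients.

Everything here consumes 100-vectors (one value per transition type) from
one or more :class:`~hbnet.network.AdjacencySuite` objects: pairwise
correlations, conic-section fits of coefficient scatter (with hyperbola
geometry), transition-Class extrema, sign-reversal contingency tables,
contralateral t'-normalization, flux-vector amplitudes, double-reciprocal
(Lineweaver-Burk) regressions and their comparisons, and marker-group tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .hb_signal import COMPONENTS
from .network import COEFFICIENT_CLASSES, AdjacencySuite
from .state_space import (
    N_STATES,
    N_TRANSITION_TYPES,
    StateGeometry,
    decode_transition,
    transition_class,
    transition_types,
)

__all__ = [
    "ConicFit",
    "LBFit",
    "LBSubset",
    "DegenerateConicError",
    "adjacency_correlation",
    "correlation_table",
    "conic_fit",
    "per_state_conic_fits",
    "class_extrema",
    "sign_reversal_table",
    "tprime_scores",
    "vector_amplitude",
    "lineweaver_burk",
    "compare_regressions",
    "rank_order_category",
    "marker_group_tests",
]


class DegenerateConicError(ValueError):
    """Raised when the scatter does not determine a conic."""


def _auto_scale(v: np.ndarray) -> float:
    """Multiplicative factor bringing a coordinate's spread to O(1)."""
    spread = float(np.std(v))
    if spread == 0.0:
        spread = float(np.max(np.abs(v))) or 1.0
    return 1.0 / spread


# ---------------------------------------------------------------------------
# pairwise correlation

def adjacency_correlation(coef_a: np.ndarray, coef_b: np.ndarray) -> float:
    """Pearson r over jointly non-missing transition types."""
    a = np.asarray(coef_a, dtype=float)
    b = np.asarray(coef_b, dtype=float)
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 3:
        raise ValueError(f"need >= 3 jointly available types, have {int(ok.sum())}")
    return float(stats.pearsonr(a[ok], b[ok]).statistic)


def correlation_table(suite: AdjacencySuite) -> pd.DataFrame:
    """All 153 unique pairwise correlations among the 18 coefficient classes."""
    rows = []
    for name_a, name_b in combinations(COEFFICIENT_CLASSES, 2):
        rows.append(
            {
                "class_a": name_a,
                "class_b": name_b,
                "r": adjacency_correlation(suite[name_a], suite[name_b]),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# conic fitting

@dataclass
class ConicFit:
    """General conic A x^2 + B xy + C y^2 + D x + E y + F = 0 (unit-norm)."""

    coeffs: Tuple[float, float, float, float, float, float]
    kind: str                      # ellipse | parabola | hyperbola | degenerate
    rms_algebraic_residual: float
    n: int
    center: Optional[Tuple[float, float]] = None
    axis_angle: Optional[float] = None       # transverse/major axis angle, rad
    vertices: Optional[np.ndarray] = None    # (2, 2) for hyperbolas
    foci: Optional[np.ndarray] = None        # (2, 2) for hyperbolas
    degenerate: bool = False

    @property
    def discriminant(self) -> float:
        a, b, c, *_ = self.coeffs
        return b * b - 4.0 * a * c

    def evaluate(self, x, y):
        a, b, c, d, e, f = self.coeffs
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return a * x * x + b * x * y + c * y * y + d * x + e * y + f


def _classify(coeffs: np.ndarray) -> str:
    """Conic kind from the discriminant sign (coeffs assumed unit-norm)."""
    a, b, c, d, e, f = coeffs
    disc = b * b - 4.0 * a * c
    m3 = np.array([[a, b / 2, d / 2], [b / 2, c, e / 2], [d / 2, e / 2, f]])
    if abs(np.linalg.det(m3)) < 1e-12:
        return "degenerate"
    if disc > 0:
        return "hyperbola"
    if disc < 0:
        return "ellipse"
    return "parabola"


def _hyperbola_geometry(coeffs: np.ndarray):
    """Center, transverse-axis angle, vertices and foci of a hyperbola."""
    a, b, c, d, e, f = coeffs
    q = np.array([[a, b / 2], [b / 2, c]])
    rhs = -0.5 * np.array([d, e])
    center = np.linalg.solve(q, rhs)
    f_c = float(
        a * center[0] ** 2 + b * center[0] * center[1] + c * center[1] ** 2
        + d * center[0] + e * center[1] + f
    )
    lam, vecs = np.linalg.eigh(q)
    # canonical: lam1*X^2 + lam2*Y^2 = -f_c ; transverse axis has positive
    # squared semi-axis (-f_c / lam_i > 0)
    with np.errstate(divide="ignore"):
        ax2 = -f_c / lam
    trans = int(np.argmax(ax2))
    a2 = ax2[trans]
    b2 = -ax2[1 - trans]
    if not (a2 > 0 and b2 > 0):
        raise DegenerateConicError("inconsistent hyperbola canonical form")
    u = vecs[:, trans]
    semi = np.sqrt(a2)
    focal = np.sqrt(a2 + b2)
    vertices = np.array([center + semi * u, center - semi * u])
    foci = np.array([center + focal * u, center - focal * u])
    angle = float(np.arctan2(u[1], u[0]) % np.pi)
    return tuple(center), angle, vertices, foci


def conic_fit(points: np.ndarray, prescale_x: float = 1.0) -> ConicFit:
    """Least-squares general-conic fit via a generalized eigenproblem.

    Minimizes the algebraic residual ||D a|| subject to the quadratic-part
    normalization A^2 + B^2/2 + C^2 = 1 (a generalized eigenvector problem),
    which admits conics of every kind.  ``prescale_x`` multiplies the
    abscissa during fitting for numerical stability; reported coefficients
    are in the original units.  Collinear or otherwise rank-deficient input
    yields a degenerate fit (flagged), not an exception, unless no solution
    exists at all.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array")
    pts = pts[np.all(np.isfinite(pts), axis=1)]
    n = len(pts)
    if n < 6:
        raise ValueError(f"need >= 6 points for a conic fit, have {n}")

    # work in rescaled coordinates (user prescale plus an automatic
    # normalization to O(1) spread); coefficients are reported, and the
    # residual evaluated, in original units
    sx = prescale_x * _auto_scale(pts[:, 0] * prescale_x)
    sy = _auto_scale(pts[:, 1])
    x = pts[:, 0] * sx
    y = pts[:, 1] * sy
    design = np.column_stack([x * x, x * y, y * y, x, y, np.ones_like(x)])
    scatter = design.T @ design
    constraint = np.diag([1.0, 0.5, 1.0, 0.0, 0.0, 0.0])

    try:
        w, v = linalg.eig(scatter, constraint)
    except linalg.LinAlgError as err:  # pragma: no cover
        raise DegenerateConicError(str(err)) from err
    w = np.real(w)
    v = np.real(v)
    tol = 1e-9 * max(1.0, float(np.abs(w[np.isfinite(w)]).max(initial=0.0)))
    ok = np.isfinite(w) & (w > -tol)
    if not ok.any():
        raise DegenerateConicError("generalized eigenproblem has no valid solution")
    best = np.flatnonzero(ok)[np.argmin(w[ok])]
    scaled = v[:, best]
    scaled = scaled / np.linalg.norm(scaled)
    kind = _classify(scaled)

    # substitute x -> sx*x, y -> sy*y to return to original units
    coeffs = scaled * np.array([sx * sx, sx * sy, sy * sy, sx, sy, 1.0])
    coeffs = coeffs / np.linalg.norm(coeffs)

    xo, yo = pts[:, 0], pts[:, 1]
    resid = (
        coeffs[0] * xo * xo + coeffs[1] * xo * yo + coeffs[2] * yo * yo
        + coeffs[3] * xo + coeffs[4] * yo + coeffs[5]
    )
    rms = float(np.sqrt(np.mean(resid ** 2)))
    fit = ConicFit(
        coeffs=tuple(float(c) for c in coeffs),
        kind=kind,
        rms_algebraic_residual=rms,
        n=n,
        degenerate=(kind == "degenerate"),
    )
    if kind == "hyperbola":
        try:
            center, angle, vertices, foci = _hyperbola_geometry(coeffs)
            fit.center = center
            fit.axis_angle = angle
            fit.vertices = vertices
            fit.foci = foci
        except (DegenerateConicError, np.linalg.LinAlgError):
            fit.degenerate = True
    return fit


def per_state_conic_fits(
    x: np.ndarray,
    y: np.ndarray,
    group_by: str = "pre_state",
    prescale_x: float = 1.0,
) -> Dict[int, Optional[ConicFit]]:
    """One conic fit per state grouping of the 100 transition types.

    ``group_by='pre_state'`` groups types by s1 (ten groups of ten points);
    ``'post_state'`` groups by s2.  Degenerate or infeasible groups map to
    fits flagged degenerate, or None when fewer than 6 finite points exist.
    """
    if group_by not in ("pre_state", "post_state"):
        raise ValueError("group_by must be 'pre_state' or 'post_state'")
    k = np.arange(1, N_TRANSITION_TYPES + 1)
    s1, s2 = decode_transition(k)
    labels = s1 if group_by == "pre_state" else s2
    out: Dict[int, Optional[ConicFit]] = {}
    for state in range(1, N_STATES + 1):
        sel = labels == state
        pts = np.column_stack([np.asarray(x)[sel], np.asarray(y)[sel]])
        pts = pts[np.all(np.isfinite(pts), axis=1)]
        if len(pts) < 6:
            out[state] = None
            continue
        try:
            out[state] = conic_fit(pts, prescale_x=prescale_x)
        except DegenerateConicError:
            out[state] = None
    return out


# ---------------------------------------------------------------------------
# class trends and sign-reversal tables

def class_extrema(coef_x: np.ndarray, coef_y: np.ndarray) -> pd.DataFrame:
    """Per transition Class (0..5), maxima of |x| and |y| over member types."""
    k = np.arange(1, N_TRANSITION_TYPES + 1)
    s1, s2 = decode_transition(k)
    m = transition_class(s1, s2)
    x = np.asarray(coef_x, dtype=float)
    y = np.asarray(coef_y, dtype=float)
    rows = []
    for cls in range(6):
        sel = m == cls
        with np.errstate(invalid="ignore"):
            rows.append(
                {
                    "class_m": cls,
                    "n_types": int(sel.sum()),
                    "max_abs_x": float(np.nanmax(np.abs(x[sel]))) if np.isfinite(x[sel]).any() else np.nan,
                    "max_abs_y": float(np.nanmax(np.abs(y[sel]))) if np.isfinite(y[sel]).any() else np.nan,
                }
            )
    return pd.DataFrame(rows)


def _reversal_flags(geometry: StateGeometry, component: str) -> np.ndarray:
    return np.array(
        [t.reversal_flags[component] for t in transition_types(geometry)], dtype=bool
    )


def _table1_values(suite: AdjacencySuite, coefficient: str) -> np.ndarray:
    """Coefficient vector used in the sign-reversal table.

    ``"abs_mean_<comp>"`` denotes the absolute value of the average of the
    pre- and post-transition means for that component.
    """
    if coefficient.startswith("abs_mean_"):
        comp = coefficient[len("abs_mean_"):]
        if comp not in COMPONENTS:
            raise ValueError(f"unknown component in {coefficient!r}")
        return np.abs(
            0.5 * (suite[f"mu_pre_{comp}"] + suite[f"mu_post_{comp}"])
        )
    return np.asarray(suite[coefficient], dtype=float)


def sign_reversal_table(
    group_suites: Dict[str, Sequence[AdjacencySuite]],
    geometry: StateGeometry,
    component: str = "total",
    coefficients: Sequence[str] = ("P", "tau_pre", "abs_mean_sat", "abs_mean_total"),
) -> pd.DataFrame:
    """Category-'0'/'1' means and tests, per coefficient and subject group.

    Category '1' contains transition types whose ``component`` sign reverses
    between pre and post states; category '0' contains the non-reversing
    types with the main diagonal excluded.  Per group: mean per category and
    a Welch (unequal-variance) t-test between categories over per-subject
    mean vectors.  When exactly two groups are supplied, a correlated-samples
    (paired over transition types) t-test between the two groups' per-type
    means is reported per category.
    """
    flags = _reversal_flags(geometry, component)
    k = np.arange(1, N_TRANSITION_TYPES + 1)
    s1, s2 = decode_transition(k)
    diag = s1 == s2
    cat1 = flags
    cat0 = ~flags & ~diag
    if not cat0.any() or not cat1.any():
        raise ValueError("one of the reversal categories is empty")

    group_names = list(group_suites)
    rows = []
    per_group_type_means: Dict[Tuple[str, str], Dict[str, np.ndarray]] = {}
    for gname in group_names:
        suites = list(group_suites[gname])
        if not suites:
            raise ValueError(f"group {gname!r} has no suites")
        for coefficient in coefficients:
            values = np.stack([_table1_values(s, coefficient) for s in suites])
            import warnings as _w
            with _w.catch_warnings():
                _w.simplefilter("ignore", RuntimeWarning)
                type_mean = np.nanmean(values, axis=0)
            v0 = type_mean[cat0]
            v1 = type_mean[cat1]
            v0 = v0[np.isfinite(v0)]
            v1 = v1[np.isfinite(v1)]
            t = stats.ttest_ind(v0, v1, equal_var=False)
            pval = float(t.pvalue)
            if not np.isfinite(pval) and np.isclose(np.mean(v0), np.mean(v1)):
                pval = 1.0  # zero-variance, equal-mean degenerate case
            rows.append(
                {
                    "coefficient": coefficient,
                    "group": gname,
                    "mean_0": float(np.mean(v0)),
                    "mean_1": float(np.mean(v1)),
                    "n_0": len(v0),
                    "n_1": len(v1),
                    "p_0_vs_1": pval,
                }
            )
            per_group_type_means[(gname, coefficient)] = {
                "0": type_mean[cat0],
                "1": type_mean[cat1],
            }

    if len(group_names) == 2:
        g1, g2 = group_names
        for coefficient in coefficients:
            extra = {"coefficient": coefficient, "group": f"{g1}-vs-{g2}"}
            for cat in ("0", "1"):
                a = per_group_type_means[(g1, coefficient)][cat]
                b = per_group_type_means[(g2, coefficient)][cat]
                ok = np.isfinite(a) & np.isfinite(b)
                t = stats.ttest_rel(a[ok], b[ok])
                extra[f"p_paired_{cat}"] = float(t.pvalue)
            rows.append(extra)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# t'-scores, vector amplitudes, rank-order categories

def tprime_scores(x_breast: np.ndarray, ref_breast: np.ndarray) -> np.ndarray:
    """Standardize a coefficient vector by the contralateral reference.

    t'_k = (x_k - mean(ref)) / sd(ref), with the reference statistics taken
    over all 100 transition types (missing types excluded).
    """
    x = np.asarray(x_breast, dtype=float)
    ref = np.asarray(ref_breast, dtype=float)
    if x.shape != ref.shape:
        raise ValueError("breast and reference vectors must have equal length")
    ref_ok = ref[np.isfinite(ref)]
    if len(ref_ok) < 2:
        raise ValueError("reference vector has too few available types")
    m = float(np.mean(ref_ok))
    s = float(np.std(ref_ok, ddof=1))
    if s <= 0:
        raise ValueError("reference standard deviation is zero")
    return (x - m) / s


def vector_amplitude(
    t_total: np.ndarray, t_sat: np.ndarray, t_dwellflux: np.ndarray
) -> np.ndarray:
    """Euclidean norm of the three t' components, per transition type."""
    arrs = [np.asarray(a, dtype=float) for a in (t_total, t_sat, t_dwellflux)]
    if len({a.shape for a in arrs}) != 1:
        raise ValueError("t' vectors must be aligned")
    return np.sqrt(arrs[0] ** 2 + arrs[1] ** 2 + arrs[2] ** 2)


#: Rank-order categories over (|t'_total|, |t'_sat|, |t'_dwell|).
#: Orderings where the dwell term is largest fall into the 'other' bucket.
_RANK_CATEGORIES = {
    ("total", "sat", "dwell"): 1,
    ("total", "dwell", "sat"): 2,
    ("sat", "total", "dwell"): 3,
    ("sat", "dwell", "total"): 4,
}


def rank_order_category(
    t_total: np.ndarray, t_sat: np.ndarray, t_dwellflux: np.ndarray
) -> np.ndarray:
    """Category 1-4 (or 0 = 'other') per type from |t'| magnitude ordering.

    Ties are broken by the fixed component precedence total > sat > dwell.
    """
    mags = np.stack(
        [np.abs(np.asarray(v, dtype=float)) for v in (t_total, t_sat, t_dwellflux)]
    )
    names = ("total", "sat", "dwell")
    out = np.zeros(mags.shape[1], dtype=int)
    for k in range(mags.shape[1]):
        col = mags[:, k]
        if not np.all(np.isfinite(col)):
            out[k] = 0
            continue
        # stable sort on negated magnitude: precedence order wins ties
        order = sorted(range(3), key=lambda i: (-col[i], i))
        out[k] = _RANK_CATEGORIES.get(tuple(names[i] for i in order), 0)
    return out


# ---------------------------------------------------------------------------
# Lineweaver-Burk analysis

@dataclass(frozen=True)
class LBSubset:
    """Declarative transition-type filter for L-B fits.

    ``classes`` restricts membership by transition Class; ``exclude_region``
    is an optional rectangle in *plot* coordinates, given as
    (x_max, y_min): points with x < x_max and y > y_min are excluded
    (the caption-style corner rectangle).
    """

    classes: Tuple[int, ...] = (0, 1, 2, 3, 4, 5)
    exclude_region: Optional[Tuple[float, float]] = None

    def class_mask(self) -> np.ndarray:
        k = np.arange(1, N_TRANSITION_TYPES + 1)
        s1, s2 = decode_transition(k)
        return np.isin(transition_class(s1, s2), self.classes)

    def region_mask(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        if self.exclude_region is None:
            return np.ones_like(np.asarray(x, dtype=float), dtype=bool)
        x_max, y_min = self.exclude_region
        return ~((np.asarray(x) < x_max) & (np.asarray(y) > y_min))


@dataclass
class LBFit:
    """OLS line through double-reciprocal coordinates."""

    slope: float
    intercept: float
    r: float
    p: float
    slope_se: float
    intercept_se: float
    n: int
    transform: str
    subset: LBSubset
    n_dropped: int = 0
    x: np.ndarray = field(default=None, repr=False)
    y: np.ndarray = field(default=None, repr=False)

    @property
    def vmax(self) -> float:
        """Saturation level under the enzyme analogy (reciprocal transform)."""
        return 1.0 / self.intercept

    @property
    def km(self) -> float:
        """Half-saturation constant under the enzyme analogy."""
        return self.slope / self.intercept


def lineweaver_burk(
    P: np.ndarray,
    y: np.ndarray,
    subset: LBSubset = LBSubset(),
    transform: str = "reciprocal",
) -> LBFit:
    """Fit transformed 1/|y| against 1/P over a declarative subset.

    ``transform`` is ``'reciprocal'`` (y -> 1/|y|) or ``'log10-reciprocal'``
    (y -> log10(1/|y|)).  Non-positive P or zero |y| points are dropped with
    a logged count.  The exclusion region of ``subset`` applies in the
    transformed plot coordinates.
    """
    if transform not in ("reciprocal", "log10-reciprocal"):
        raise ValueError(f"unknown transform {transform!r}")
    P = np.asarray(P, dtype=float)
    y = np.asarray(y, dtype=float)
    if P.shape != y.shape:
        raise ValueError("P and y must be aligned")

    mask = subset.class_mask() if P.shape == (N_TRANSITION_TYPES,) else np.ones(P.shape, bool)
    usable = mask & np.isfinite(P) & np.isfinite(y) & (P > 0) & (np.abs(y) > 0)
    n_dropped = int(mask.sum() - usable.sum())

    xv = 1.0 / P[usable]
    yv = 1.0 / np.abs(y[usable])
    if transform == "log10-reciprocal":
        yv = np.log10(yv)
    keep = subset.region_mask(xv, yv)
    n_dropped += int((~keep).sum())
    xv, yv = xv[keep], yv[keep]
    if len(xv) < 3:
        raise ValueError(f"subset leaves too few points for a fit ({len(xv)})")

    res = stats.linregress(xv, yv)
    return LBFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r=float(res.rvalue),
        p=float(res.pvalue),
        slope_se=float(res.stderr),
        intercept_se=float(res.intercept_stderr),
        n=len(xv),
        transform=transform,
        subset=subset,
        n_dropped=n_dropped,
        x=xv,
        y=yv,
    )


def compare_regressions(fit1: LBFit, fit2: LBFit) -> Tuple[float, float]:
    """Two-sample t-tests on slopes and intercepts of two independent fits.

    Uses the coefficient standard errors with pooled df = n1 + n2 - 4.
    Returns (p_slope, p_intercept), two-sided.
    """
    df = fit1.n + fit2.n - 4
    if df < 1:
        raise ValueError("too few points to compare regressions")
    out = []
    for b1, se1, b2, se2 in (
        (fit1.slope, fit1.slope_se, fit2.slope, fit2.slope_se),
        (fit1.intercept, fit1.intercept_se, fit2.intercept, fit2.intercept_se),
    ):
        se = np.hypot(se1, se2)
        if se == 0:
            out.append(1.0 if b1 == b2 else 0.0)
            continue
        t = (b1 - b2) / se
        out.append(float(2.0 * stats.t.sf(abs(t), df)))
    return out[0], out[1]


# ---------------------------------------------------------------------------
# biomarker-group comparisons

def marker_group_tests(
    amplitudes: Dict[str, np.ndarray],
    labels: Dict[str, bool],
    classes: Tuple[int, ...] = (3, 4, 5),
    categories: Optional[np.ndarray] = None,
) -> pd.DataFrame:
    """Welch t-tests of per-type mean amplitudes between marker groups.

    ``amplitudes`` maps subject id -> 100-vector of vector amplitudes;
    ``labels`` maps subject id -> marker status (True = positive).  Tests
    are run for all Classes 3-5 types together and, when ``categories``
    (per-type rank-order labels) is given, per category 1-4.  A
    Benjamini-Hochberg adjusted column is included for transparency only.
    """
    subjects = sorted(amplitudes)
    pos = [s for s in subjects if labels[s]]
    neg = [s for s in subjects if not labels[s]]
    if not pos or not neg:
        raise ValueError("need at least one subject in each marker group")
    k = np.arange(1, N_TRANSITION_TYPES + 1)
    s1, s2 = decode_transition(k)
    in_class = np.isin(transition_class(s1, s2), classes)

    def per_type_mean(ids):
        return np.nanmean(np.stack([amplitudes[s] for s in ids]), axis=0)

    mean_pos = per_type_mean(pos)
    mean_neg = per_type_mean(neg)

    selections: List[Tuple[str, np.ndarray]] = [("all_classes_3_5", in_class)]
    if categories is not None:
        categories = np.asarray(categories)
        for cat in (1, 2, 3, 4):
            selections.append((f"rank_order_{cat}", in_class & (categories == cat)))

    rows = []
    for name, sel in selections:
        a = mean_pos[sel]
        b = mean_neg[sel]
        ok = np.isfinite(a) & np.isfinite(b)
        a, b = a[ok], b[ok]
        if len(a) < 2:
            rows.append({"selection": name, "n_types": len(a), "p": np.nan,
                         "mean_pos": np.nan, "sd_pos": np.nan,
                         "mean_neg": np.nan, "sd_neg": np.nan})
            continue
        t = stats.ttest_ind(a, b, equal_var=False)
        rows.append(
            {
                "selection": name,
                "n_types": len(a),
                "mean_pos": float(np.mean(a)),
                "sd_pos": float(np.std(a, ddof=1)),
                "mean_neg": float(np.mean(b)),
                "sd_neg": float(np.std(b, ddof=1)),
                "p": float(t.pvalue),
            }
        )
    df = pd.DataFrame(rows)
    ok = df["p"].notna()
    df.loc[ok, "p_bh"] = _benjamini_hochberg(df.loc[ok, "p"].to_numpy())
    return df


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p)
    adj = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * n / rank)
        adj[idx] = running
    return adj
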