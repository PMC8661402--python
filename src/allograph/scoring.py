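"""Distance-debiased quantile scoring and surrogate-site significance.

Raw propensities decay and transient half-times grow with distance from
the source, so raw values cannot be compared across the structure.  To
remove this bias, linear quantile regressions of log10(measure) on
distance are fitted over a grid of quantile levels tau, and every item
(bond or atom) receives as score the highest tau whose regression line
it beats among items equidistant from the source.  Scores live in
[0, 1] and are approximately uniform under the null, which makes them
comparable between runs and structures.

A site of interest is scored by its mean residue quantile score and
compared against surrogate sites sampled with the same residue count
and diameter anywhere in the structure; a percentile bootstrap over the
surrogate means yields a 95% confidence interval and an empirical
p-value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.optimize import linprog

from .structure_io import ResidueKey, Structure

__all__ = [
    "QuantileFit",
    "QuantileScoreTable",
    "SiteScore",
    "DetectionReport",
    "fit_quantile",
    "quantile_scores",
    "default_tau_grid",
    "residue_coordinates",
    "sample_surrogate_sites",
    "score_site",
    "detection_report",
    "log10_floored",
]

LOG_FLOOR = 1e-300
_TOL = 1e-9  # tolerance for item-vs-line comparisons

_STANDARD_AA = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}


def log10_floored(values: np.ndarray, floor: float = LOG_FLOOR) -> np.ndarray:
    """log10 with values floored at a tiny positive constant."""
    return np.log10(np.maximum(np.asarray(values, dtype=float), floor))


@dataclass(frozen=True)
class QuantileFit:
    """Linear quantile regression y = intercept + slope * x at level tau."""

    tau: float
    intercept: float
    slope: float

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(x, dtype=float)


def pinball_loss(u: np.ndarray, tau: float) -> np.ndarray:
    """rho_tau(u) = u * (tau - 1{u < 0})."""
    u = np.asarray(u, dtype=float)
    return u * (tau - (u < 0))


def fit_quantile(x: np.ndarray, y: np.ndarray, tau: float) -> QuantileFit:
    """Fit a linear quantile regression by exact linear programming.

    Minimises sum_i rho_tau(y_i - a - b x_i) via the standard LP
    split into positive/negative residual parts, solved with HiGHS
    (deterministic).  Degenerate x (all values equal) falls back to an
    intercept-only fit at the empirical tau-quantile.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if not 0.0 < tau < 1.0:
        raise ValueError("tau must be in (0, 1)")
    if not np.all(np.isfinite(y)) or not np.all(np.isfinite(x)):
        raise ValueError("x and y must be finite")
    n = len(y)
    if np.ptp(x) == 0.0:
        q = float(np.quantile(y, tau, method="inverted_cdf"))
        return QuantileFit(tau, q, 0.0)
    # variables: [a, b, u+ (n), u- (n)]
    ones = np.ones(n)
    A_eq = sparse.hstack(
        [
            sparse.csc_matrix(ones[:, None]),
            sparse.csc_matrix(x[:, None]),
            sparse.eye(n, format="csc"),
            -sparse.eye(n, format="csc"),
        ],
        format="csc",
    )
    c = np.concatenate([[0.0, 0.0], tau * ones, (1.0 - tau) * ones])
    bounds = [(None, None), (None, None)] + [(0.0, None)] * (2 * n)
    res = linprog(c, A_eq=A_eq, b_eq=y, bounds=bounds, method="highs")
    if not res.success:
        raise RuntimeError(f"quantile LP failed at tau={tau}: {res.message}")
    a, b = res.x[0], res.x[1]
    return QuantileFit(tau, float(a), float(b))


def default_tau_grid() -> np.ndarray:
    """Quantile levels 0.01 ... 0.99 in steps of 0.01, plus 0.995."""
    grid = np.round(np.arange(0.01, 1.00, 0.01), 2)
    return np.append(grid, 0.995)


@dataclass
class QuantileScoreTable:
    """Per-item quantile scores plus the underlying fits."""

    scores: np.ndarray
    orientation: str  # 'higher' (propensities) or 'lower' (half-times)
    tau_grid: np.ndarray
    fits: list[QuantileFit] = field(repr=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"item": np.arange(len(self.scores)), "quantile_score": self.scores}
        )


def quantile_scores(
    x: np.ndarray,
    y: np.ndarray,
    orientation: str = "higher",
    tau_grid: np.ndarray | None = None,
) -> QuantileScoreTable:
    """Assign a quantile score in [0, 1] to every item.

    For 'higher' orientation (propensities: bigger is better) the score
    of item i is the largest tau whose fitted line lies at or below
    y_i, or 0 when i falls below every line.  For 'lower' orientation
    (half-times: smaller is better) the score is 1 minus the smallest
    tau whose line lies at or above y_i, so fast atoms earn high
    scores.  Quantile crossing is resolved by sorting the fitted values
    per item.
    """
    if orientation not in ("higher", "lower"):
        raise ValueError("orientation must be 'higher' or 'lower'")
    tau = np.asarray(default_tau_grid() if tau_grid is None else tau_grid, dtype=float)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    fits = [fit_quantile(x, y, float(t)) for t in tau]
    F = np.column_stack([f.predict(x) for f in fits])  # (n, T)
    F = np.sort(F, axis=1)  # non-crossing via per-item sorting
    n, T = F.shape
    scores = np.zeros(n)
    if orientation == "higher":
        # count of sorted fitted values <= y_i (with tolerance)
        k = np.sum(F <= (y + _TOL)[:, None], axis=1)
        nonzero = k > 0
        scores[nonzero] = tau[k[nonzero] - 1]
    else:
        # first sorted fitted value >= y_i
        k = np.sum(F < (y - _TOL)[:, None], axis=1)
        within = k < T
        scores[within] = 1.0 - tau[k[within]]
    return QuantileScoreTable(scores=scores, orientation=orientation,
                              tau_grid=tau, fits=fits)


def residue_coordinates(obj) -> tuple[list[ResidueKey], np.ndarray]:
    """Representative coordinate per residue.

    For protein residues the C-alpha position is used when present;
    ligands, nucleotides and anything else fall back to the heavy-atom
    centroid.  Accepts a Structure or an AtomisticGraph.
    """
    if isinstance(obj, Structure):
        atoms = obj.atoms
        coords = obj.coords
        by_res: dict[ResidueKey, list[int]] = {}
        for i, a in enumerate(atoms):
            by_res.setdefault(a.residue_key, []).append(i)
        keys = list(by_res)
        out = np.empty((len(keys), 3))
        for r, key in enumerate(keys):
            idxs = by_res[key]
            ca = [i for i in idxs
                  if atoms[i].name == "CA" and key.res_name in _STANDARD_AA]
            if ca:
                out[r] = coords[ca[0]]
            else:
                heavy = [i for i in idxs if atoms[i].element != "H"] or idxs
                out[r] = coords[heavy].mean(axis=0)
        return keys, out
    # AtomisticGraph or anything with coords + residue_of_atom
    by_res = {}
    for i, k in enumerate(obj.residue_of_atom):
        by_res.setdefault(k, []).append(i)
    keys = list(by_res)
    out = np.array([obj.coords[by_res[k]].mean(axis=0) for k in keys])
    return keys, out


def site_diameter(coords: np.ndarray) -> float:
    """Max pairwise distance of the representative coordinates."""
    if len(coords) < 2:
        return 0.0
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=2)
    return float(d.max())


def sample_surrogate_sites(
    residue_keys: Sequence[ResidueKey],
    residue_coords: np.ndarray,
    k: int,
    diameter: float,
    n: int = 1000,
    seed: int = 1000,
    tolerance: float = 0.10,
    max_retries: int = 100,
) -> list[tuple[ResidueKey, ...]]:
    """Sample ``n`` random sites matched in residue count and diameter.

    Each surrogate draws a seed residue uniformly, collects the
    residues within the query diameter around it and draws ``k``
    without replacement, accepting the draw when its own diameter stays
    within ``diameter * (1 + tolerance)``.  After ``max_retries``
    failures the tolerance is relaxed by 5 percentage points (logged as
    a warning) and sampling continues.  Deterministic under ``seed``.
    """
    keys = list(residue_keys)
    coords = np.asarray(residue_coords, dtype=float)
    if len(keys) != len(coords):
        raise ValueError("residue_keys and residue_coords length mismatch")
    if k < 1 or k > len(keys):
        raise ValueError(
            f"cannot sample sites of {k} residues from {len(keys)} residues"
        )
    rng = np.random.default_rng(seed)
    dmat = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=2)
    sites: list[tuple[ResidueKey, ...]] = []
    tol = tolerance
    while len(sites) < n:
        accepted = None
        for _ in range(max_retries):
            s = int(rng.integers(len(keys)))
            ball = np.flatnonzero(dmat[s] <= diameter * (1 + tol) + 1e-12)
            if len(ball) < k:
                continue
            pick = rng.choice(ball, size=k, replace=False)
            if k == 1 or dmat[np.ix_(pick, pick)].max() <= diameter * (1 + tol) + 1e-12:
                accepted = pick
                break
        if accepted is None:
            tol += 0.05
            warnings.warn(
                f"surrogate sampling: relaxing diameter tolerance to "
                f"{tol:.0%} after {max_retries} failed draws",
                stacklevel=2,
            )
            if tol > 1.0:
                raise RuntimeError(
                    "structure too small to host surrogate sites of the "
                    "requested size and diameter"
                )
            continue
        sites.append(tuple(keys[i] for i in sorted(accepted)))
    return sites


@dataclass
class SiteScore:
    """Mean quantile score of a site against a surrogate null."""

    site: frozenset
    mean_qs: float
    surrogate_mean: float
    ci95: tuple[float, float]
    p_emp: float
    n_surrogates: int
    surrogate_means: np.ndarray = field(repr=False)

    def to_dict(self) -> dict:
        return {
            "site": sorted(str(k) for k in self.site),
            "mean_qs": self.mean_qs,
            "surrogate_mean": self.surrogate_mean,
            "ci95": list(self.ci95),
            "p_emp": self.p_emp,
            "n_surrogates": self.n_surrogates,
        }


def score_site(
    site: Sequence[ResidueKey],
    residue_scores: Mapping[ResidueKey, float],
    surrogates: Sequence[Sequence[ResidueKey]],
    bootstrap: int = 10000,
    seed: int = 2000,
) -> SiteScore:
    """Score a site of interest against surrogate sites.

    ``mean_qs`` is the mean residue quantile score over the site;
    the surrogate null is the distribution of the same mean over the
    sampled surrogate sites.  The 95% CI is a percentile bootstrap of
    the surrogate-mean average, and the empirical p-value uses the
    add-one correction p = (1 + #{surrogate >= site}) / (n + 1).
    """
    site = list(site)
    missing = [k for k in site if k not in residue_scores]
    if missing:
        raise KeyError(
            f"site residues without scores: {[str(k) for k in missing]}"
        )
    mean_qs = float(np.mean([residue_scores[k] for k in site]))
    surr_means = []
    for surr in surrogates:
        vals = [residue_scores[k] for k in surr if k in residue_scores]
        if not vals:
            continue
        surr_means.append(float(np.mean(vals)))
    if not surr_means:
        raise ValueError("no scorable surrogate sites")
    surr_means = np.asarray(surr_means)
    n = len(surr_means)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(bootstrap, n))
    boot = surr_means[idx].mean(axis=1)
    ci = (float(np.percentile(boot, 2.5)), float(np.percentile(boot, 97.5)))
    p_emp = float((1 + np.sum(surr_means >= mean_qs)) / (n + 1))
    return SiteScore(
        site=frozenset(site),
        mean_qs=mean_qs,
        surrogate_mean=float(surr_means.mean()),
        ci95=ci,
        p_emp=p_emp,
        n_surrogates=n,
        surrogate_means=surr_means,
    )


@dataclass
class DetectionReport:
    """Four stand-in detection measures plus the any-of decision."""

    s1_mean_qs: float
    s2_p_emp: float
    s3_max_residue_score: float
    s4_fraction_above_half: float

    S1_THRESHOLD = 0.9
    S2_THRESHOLD = 0.05
    S3_THRESHOLD = 0.95
    S4_THRESHOLD = 0.5

    @property
    def criteria(self) -> dict[str, bool]:
        return {
            "S1": self.s1_mean_qs >= self.S1_THRESHOLD,
            "S2": self.s2_p_emp <= self.S2_THRESHOLD,
            "S3": self.s3_max_residue_score >= self.S3_THRESHOLD,
            "S4": self.s4_fraction_above_half > self.S4_THRESHOLD,
        }

    @property
    def detected(self) -> bool:
        return any(self.criteria.values())

    def to_dict(self) -> dict:
        return {
            "S1": self.s1_mean_qs,
            "S2": self.s2_p_emp,
            "S3": self.s3_max_residue_score,
            "S4": self.s4_fraction_above_half,
            "criteria": self.criteria,
            "detected": self.detected,
        }


def score_bonds(result, tau_grid: np.ndarray | None = None) -> QuantileScoreTable:
    """Quantile-score the non-source bonds of a propensity result.

    Adds a ``quantile_score`` column to ``result.bond_table`` (NaN for
    source bonds) and returns the score table.  Uses distance from
    source as the covariate and log10 normalised propensity as the
    response, higher-better orientation.
    """
    tbl = result.bond_table
    mask = ~tbl["is_source"].to_numpy()
    x = tbl.loc[mask, "distance_A"].to_numpy()
    y = log10_floored(tbl.loc[mask, "norm_propensity"].to_numpy())
    qt = quantile_scores(x, y, "higher", tau_grid)
    col = np.full(len(tbl), np.nan)
    col[mask] = qt.scores
    tbl["quantile_score"] = col
    return qt


def score_atoms(result, tau_grid: np.ndarray | None = None) -> QuantileScoreTable:
    """Quantile-score the non-source atoms of a transient result.

    Lower-better orientation: atoms reached quickly (small half-time)
    earn high scores.  Adds a ``quantile_score`` column to
    ``result.atom_table`` (NaN for source atoms).
    """
    tbl = result.atom_table
    mask = ~tbl["is_source"].to_numpy()
    x = tbl.loc[mask, "distance_A"].to_numpy()
    y = log10_floored(tbl.loc[mask, "t_half"].to_numpy())
    qt = quantile_scores(x, y, "lower", tau_grid)
    col = np.full(len(tbl), np.nan)
    col[mask] = qt.scores
    tbl["quantile_score"] = col
    return qt


def residue_quantile_scores(
    result,
    mode: str = "aggregate",
    tau_grid: np.ndarray | None = None,
    transient_stat: str = "min",
) -> dict[ResidueKey, float]:
    """Per-residue quantile scores for a propensity or transient result.

    ``aggregate`` (default) re-runs the quantile procedure on the
    residue-aggregated measure (summed bond propensity, or the
    min/mean atom half-time) against the residue's minimum distance
    from the source.  ``mean`` instead averages the member items'
    quantile scores (bonds count for both endpoint residues).  Source
    residues are excluded either way.
    """
    rtbl = result.residue_table
    is_propensity = "propensity" in rtbl.columns
    mask = ~rtbl["is_source"].to_numpy()
    keys = [k for k, m in zip(rtbl["residue_key"], mask) if m]
    if mode == "aggregate":
        x = rtbl.loc[mask, "distance_A"].to_numpy()
        if is_propensity:
            y = log10_floored(rtbl.loc[mask, "propensity"].to_numpy())
            qt = quantile_scores(x, y, "higher", tau_grid)
        else:
            col = {"min": "t_half_min", "mean": "t_half_mean"}[transient_stat]
            y = log10_floored(rtbl.loc[mask, col].to_numpy())
            qt = quantile_scores(x, y, "lower", tau_grid)
        return dict(zip(keys, qt.scores))
    if mode != "mean":
        raise ValueError("mode must be 'aggregate' or 'mean'")
    name_to_key = dict(zip(rtbl["residue"], rtbl["residue_key"]))
    acc: dict[ResidueKey, list[float]] = {}
    if is_propensity:
        tbl = result.bond_table
        if "quantile_score" not in tbl.columns:
            score_bonds(result, tau_grid)
        for _, row in tbl[~tbl["is_source"]].iterrows():
            for rname in {row["residue_u"], row["residue_v"]}:
                acc.setdefault(name_to_key[rname], []).append(row["quantile_score"])
    else:
        tbl = result.atom_table
        if "quantile_score" not in tbl.columns:
            score_atoms(result, tau_grid)
        for _, row in tbl[~tbl["is_source"]].iterrows():
            acc.setdefault(name_to_key[row["residue"]], []).append(
                row["quantile_score"]
            )
    return {k: float(np.mean(v)) for k, v in acc.items() if k in set(keys)}


def detection_report(
    site_score: SiteScore, residue_scores: Mapping[ResidueKey, float]
) -> DetectionReport:
    """Detection measures of a scored site.

    S1: site mean quantile score; S2: empirical p-value; S3: maximum
    residue score within the site; S4: fraction of site residues
    scoring above 0.5.  The site counts as detected when any single
    criterion is met.
    """
    vals = np.array([residue_scores[k] for k in site_score.site])
    return DetectionReport(
        s1_mean_qs=site_score.mean_qs,
        s2_p_emp=site_score.p_emp,
        s3_max_residue_score=float(vals.max()),
        s4_fraction_above_half=float(np.mean(vals > 0.5)),
    )
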