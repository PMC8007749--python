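"""Stimulation-field connectomics: fibre recruitment, R-maps, fibre t-scores.

Given a streamline connectome, a per-hemisphere E-field and VAT for each
participant, and per-participant clinical improvement, this module
implements the three outcome-association methods:

1. **Voxel-wise R-map with leave-one-out prediction.**  Each participant's
   stimulation field is turned into a connectivity profile (weighted fibre
   visits per voxel); profiles are correlated voxel-wise with improvement
   (Spearman, average ranks) to form an R-map; a left-out participant's
   improvement is predicted by the Fisher-z spatial correlation between
   their profile and the remaining cohort's R-map.
2. **Discriminative fibre t-scores.**  Each fibre is tested (two-sided
   two-sample Student t) between participants whose VAT encompasses it and
   those whose VAT does not; the top 5% of positively scoring fibres are
   selected.
3. **ROI connectivity and mixed-model association.**  Profile mass is
   aggregated per parcellation label and entered, interacted with time, in
   the longitudinal mixed model.

A generic tract-recruitment scorer reproduces the atlas-replication
analysis: total recruitment weight of a named tract per participant,
correlated with improvement.

All streamline geometry is resampled at 0.5 mm steps everywhere, so
recruitment weighting, profile construction and connected/unconnected
group assignment see the same sample points.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats

from .connectome import Connectome
from .grids import GridSpec
from .stimulation_model import ScalarField, VAT
from . import clinical_outcomes as co

RESAMPLE_STEP_MM = 0.5
FISHER_Z_CAP = 1.0 - 1e-7   # |r| cap before atanh
DEFAULT_MIN_NONZERO = 3     # voxel validity: participants with nonzero profile
DEFAULT_TOP_FRACTION = 0.05
DEFAULT_MIN_GROUP = 2


class ConnectomicsError(ValueError):
    """Invalid input to a connectomics computation."""


# ---------------------------------------------------------------------------
# cached streamline sampling
# ---------------------------------------------------------------------------

def _sample_table(connectome: Connectome, step: float = RESAMPLE_STEP_MM):
    """Concatenated resampled points + reduceat offsets, cached."""
    key = ("samples", float(step))
    if key not in connectome._cache:
        paths = connectome.resampled(step)
        counts = np.array([p.shape[0] for p in paths])
        offsets = np.concatenate([[0], np.cumsum(counts)[:-1]])
        pts = np.concatenate(paths, axis=0)
        connectome._cache[key] = (pts, offsets, counts)
    return connectome._cache[key]


def _voxel_table(connectome: Connectome, grid: GridSpec, step: float = RESAMPLE_STEP_MM):
    """Per-streamline distinct voxel ids on ``grid``, cached."""
    key = ("voxels", grid.shape, grid.voxel_size, grid.origin, float(step))
    if key not in connectome._cache:
        from .grids import polyline_voxels
        per = [polyline_voxels(p, grid) for p in connectome.resampled(step)]
        counts = np.array([v.size for v in per])
        ids = (np.concatenate(per) if per else np.empty(0, dtype=np.int64))
        connectome._cache[key] = (per, ids, counts)
    return connectome._cache[key]


# ---------------------------------------------------------------------------
# recruitment and profiles
# ---------------------------------------------------------------------------

@dataclass
class RecruitmentWeights:
    """Per-streamline recruitment weight in [0, 1] for one field/VAT."""

    weights: np.ndarray
    max_field: float  # normalising in-VAT field maximum (0 if VAT empty)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)


def recruit_fibres(connectome: Connectome, efield: ScalarField, vat: VAT,
                   step: float = RESAMPLE_STEP_MM) -> RecruitmentWeights:
    """E-field-weighted fibre recruitment.

    Each streamline's weight is its maximum E-field value over resampled
    points inside the VAT, normalised by the largest such value over all
    streamlines (so the fibre passing closest to an active contact gets
    weight 1).  Fibres that never enter the VAT get weight 0.
    """
    pts, offsets, _ = _sample_table(connectome, step)
    if not vat.mask.any():
        warnings.warn("empty VAT: all recruitment weights are zero", stacklevel=2)
        return RecruitmentWeights(np.zeros(len(connectome)), 0.0)
    vals = efield.sample(pts)
    vals = np.where(vat.contains(pts), vals, -1.0)
    per_max = np.maximum.reduceat(vals, offsets)
    gmax = float(per_max.max())
    if gmax <= 0:
        return RecruitmentWeights(np.zeros(len(connectome)), 0.0)
    return RecruitmentWeights(np.clip(per_max, 0.0, None) / gmax, gmax)


@dataclass
class ConnectivityProfile:
    """Per-voxel weighted fibre-visit counts for one participant-hemisphere."""

    values: np.ndarray
    grid: GridSpec
    participant_id: str | None = None
    hemisphere: str | None = None

    @property
    def flat(self) -> np.ndarray:
        return self.values.reshape(-1)

    def save(self, path) -> None:
        nib.save(nib.Nifti1Image(self.values.astype(np.float32), self.grid.affine),
                 str(path))


def connectivity_profile(weights: RecruitmentWeights, connectome: Connectome,
                         grid: GridSpec, step: float = RESAMPLE_STEP_MM,
                         participant_id: str | None = None,
                         hemisphere: str | None = None) -> ConnectivityProfile:
    """Project recruited fibres to the voxel grid.

    Every recruited streamline adds its weight exactly once to each
    distinct voxel its resampled path visits (per-streamline, per-voxel
    deduplication), so profiles are additive over disjoint fibre subsets.
    """
    w = weights.weights
    if w.shape[0] != len(connectome):
        raise ConnectomicsError("weights do not match connectome size")
    _, ids, counts = _voxel_table(connectome, grid, step)
    vals = np.zeros(grid.n_voxels)
    keep = np.repeat(w, counts)
    nz = keep > 0
    if nz.any():
        vals = np.bincount(ids[nz], weights=keep[nz], minlength=grid.n_voxels)
    return ConnectivityProfile(vals.reshape(grid.shape), grid,
                               participant_id, hemisphere)


# ---------------------------------------------------------------------------
# R-map and spatial similarity
# ---------------------------------------------------------------------------

@dataclass
class RMap:
    """Voxel-wise Spearman rho between profile values and improvement."""

    rho: np.ndarray           # grid-shaped, NaN where invalid
    valid: np.ndarray         # boolean mask of valid voxels
    grid: GridSpec
    all_invalid: bool = False

    def save(self, path) -> None:
        nib.save(nib.Nifti1Image(self.rho.astype(np.float32), self.grid.affine),
                 str(path))


def _profile_matrix(profiles: list[ConnectivityProfile]) -> tuple[np.ndarray, GridSpec]:
    grid = profiles[0].grid
    for p in profiles:
        if p.grid != grid:
            raise ConnectomicsError("profiles must share a grid")
    return np.stack([p.flat for p in profiles], axis=0), grid


def compute_rmap(profiles: list[ConnectivityProfile], improvement,
                 min_nonzero: int = DEFAULT_MIN_NONZERO) -> RMap:
    """Voxel-wise Spearman correlation of connectivity with improvement.

    Ranks use the average-rank convention for ties.  Voxels with fewer
    than ``min_nonzero`` participants showing nonzero connectivity, or with
    no variance across participants, are masked invalid (NaN).
    """
    y = np.asarray(improvement, dtype=float)
    if len(profiles) < 4:
        raise ConnectomicsError("R-map needs >= 4 participants")
    if y.shape[0] != len(profiles):
        raise ConnectomicsError("improvement length must match profiles")
    P, grid = _profile_matrix(profiles)
    rho_flat = np.full(grid.n_voxels, np.nan)
    if np.ptp(y) == 0:
        warnings.warn("constant improvement vector: R-map is all-invalid", stacklevel=2)
        return RMap(rho_flat.reshape(grid.shape), np.zeros(grid.shape, bool),
                    grid, all_invalid=True)
    valid = ((P > 0).sum(axis=0) >= min_nonzero) & (P.std(axis=0) > 0)
    if valid.any():
        R = stats.rankdata(P[:, valid], axis=0)
        ry = stats.rankdata(y)
        R = R - R.mean(axis=0)
        ry = ry - ry.mean()
        denom = np.linalg.norm(R, axis=0) * np.linalg.norm(ry)
        rho_flat[valid] = (R.T @ ry) / denom
    return RMap(rho_flat.reshape(grid.shape), valid.reshape(grid.shape), grid,
                all_invalid=not valid.any())


@dataclass(frozen=True)
class SpatialSimilarity:
    r: float
    z: float
    n_voxels: int


def spatial_similarity(profile: ConnectivityProfile, rmap: RMap,
                       min_voxels: int = 10) -> SpatialSimilarity:
    """Fisher z-transformed spatial correlation of a profile with an R-map.

    Pearson correlation over the R-map's valid voxels, then atanh, with
    |r| capped just below 1 so perfect correlations stay finite.  A profile
    with no variance over the valid voxels scores 0.
    """
    if profile.grid != rmap.grid:
        raise ConnectomicsError("profile and R-map must share a grid")
    mask = rmap.valid.reshape(-1)
    n = int(mask.sum())
    if n < min_voxels:
        raise ConnectomicsError(f"only {n} valid voxels, need >= {min_voxels}")
    x = profile.flat[mask]
    y = rmap.rho.reshape(-1)[mask]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return SpatialSimilarity(0.0, 0.0, n)
    r = float(np.corrcoef(x, y)[0, 1])
    r_c = float(np.clip(r, -FISHER_Z_CAP, FISHER_Z_CAP))
    return SpatialSimilarity(r, float(np.arctanh(r_c)), n)


# ---------------------------------------------------------------------------
# leave-one-out cross-validated prediction
# ---------------------------------------------------------------------------

class _LoocvMachine:
    """Precomputed fold structures so permutation nulls are cheap.

    For each left-out participant the validity mask and the rank-transformed
    (centred, normalised) training profiles depend only on the profiles, so
    they are computed once; evaluating a (possibly permuted) improvement
    vector is then a matrix-vector product per fold.
    """

    def __init__(self, profiles: list[ConnectivityProfile],
                 min_nonzero: int = DEFAULT_MIN_NONZERO, min_voxels: int = 10):
        P, grid = _profile_matrix(profiles)
        self.n = P.shape[0]
        if self.n < 5:
            raise ConnectomicsError("LOOCV needs >= 5 participants")
        self.folds = []
        for i in range(self.n):
            train = np.delete(np.arange(self.n), i)
            Pt = P[train]
            valid = ((Pt > 0).sum(axis=0) >= min_nonzero) & (Pt.std(axis=0) > 0)
            if valid.sum() < min_voxels:
                self.folds.append(None)  # fold excluded: R-map degenerate
                continue
            R = stats.rankdata(Pt[:, valid], axis=0)
            R = R - R.mean(axis=0)
            R = R / np.linalg.norm(R, axis=0)
            x = P[i, valid]
            if np.ptp(x) > 0:
                x = (x - x.mean()) / np.linalg.norm(x - x.mean())
            else:
                x = None
            self.folds.append((train, R, x))

    def predict(self, improvement: np.ndarray) -> np.ndarray:
        """Fisher-z predictions for each participant; NaN for excluded folds."""
        y = np.asarray(improvement, dtype=float)
        preds = np.full(self.n, np.nan)
        for i, fold in enumerate(self.folds):
            if fold is None:
                continue
            train, R, x = fold
            ry = stats.rankdata(y[train])
            ry = ry - ry.mean()
            nrm = np.linalg.norm(ry)
            if nrm == 0 or x is None:
                preds[i] = 0.0
                continue
            rho = R.T @ (ry / nrm)
            rho_c = rho - rho.mean()
            d = np.linalg.norm(rho_c)
            if d == 0:
                preds[i] = 0.0
                continue
            r = float(x @ (rho_c / d))
            preds[i] = np.arctanh(np.clip(r, -FISHER_Z_CAP, FISHER_Z_CAP))
        return preds


@dataclass
class LoocvResult:
    predictions: np.ndarray       # Fisher-z predicted scores, NaN = excluded fold
    excluded_folds: list[int]
    pearson_r: float
    pearson_p: float
    spearman_r: float
    spearman_p: float
    method: str                   # headline correlation flavour


def loocv_predict(profiles: list[ConnectivityProfile], improvement,
                  min_nonzero: int = DEFAULT_MIN_NONZERO,
                  method: str = "pearson") -> LoocvResult:
    """Leave-one-out prediction of improvement from connectivity profiles.

    For each participant an R-map is built from the others; the prediction
    is the Fisher-z spatial similarity of the left-out profile with that
    map.  Both Pearson (default headline, as in the source analysis) and
    Spearman correlations of predicted vs empirical improvement are
    reported.
    """
    if method not in ("pearson", "spearman"):
        raise ConnectomicsError("method must be 'pearson' or 'spearman'")
    y = np.asarray(improvement, dtype=float)
    machine = _LoocvMachine(profiles, min_nonzero)
    preds = machine.predict(y)
    ok = np.isfinite(preds)
    excluded = [int(i) for i in np.flatnonzero(~ok)]
    if excluded:
        warnings.warn(f"LOOCV folds excluded (degenerate R-map): {excluded}",
                      stacklevel=2)
    if ok.sum() < 3 or np.ptp(preds[ok]) == 0:
        pr = pp = sr = sp = np.nan
    else:
        pr, pp = stats.pearsonr(preds[ok], y[ok])
        sr, sp = stats.spearmanr(preds[ok], y[ok])
    return LoocvResult(preds, excluded, float(pr), float(pp), float(sr), float(sp),
                       method)


def loocv_permutation_test(profiles: list[ConnectivityProfile], improvement,
                           n_permutations: int = 100,
                           seed: int | np.random.Generator = 0,
                           min_nonzero: int = DEFAULT_MIN_NONZERO,
                           method: str = "pearson") -> tuple[float, np.ndarray, float]:
    """Permutation null for the LOOCV predicted-vs-empirical correlation.

    Returns (observed r, null r values, one-sided permutation p with the
    add-one correction p = (1 + #{null >= observed}) / (B + 1)).
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    y = np.asarray(improvement, dtype=float)
    machine = _LoocvMachine(profiles, min_nonzero)

    def corr(yvec: np.ndarray) -> float:
        preds = machine.predict(yvec)
        ok = np.isfinite(preds)
        if ok.sum() < 3 or np.ptp(preds[ok]) == 0 or np.ptp(yvec[ok]) == 0:
            return np.nan
        if method == "pearson":
            return float(stats.pearsonr(preds[ok], yvec[ok])[0])
        return float(stats.spearmanr(preds[ok], yvec[ok])[0])

    observed = corr(y)
    null = np.array([corr(rng.permutation(y)) for _ in range(n_permutations)])
    finite_null = null[np.isfinite(null)]
    p = (1.0 + np.sum(finite_null >= observed)) / (finite_null.size + 1.0)
    return observed, null, float(p)


# ---------------------------------------------------------------------------
# discriminative fibre t-scores
# ---------------------------------------------------------------------------

@dataclass
class FibreScoreResult:
    table: pd.DataFrame          # per-fibre scores and group bookkeeping
    selected: np.ndarray         # fibre ids in the selected top set
    connected: np.ndarray        # (n_participants, n_fibres) boolean


def fibre_connection_matrix(connectome: Connectome, vats: list[VAT],
                            step: float = RESAMPLE_STEP_MM) -> np.ndarray:
    """Boolean (participants x fibres): does the VAT encompass the fibre?

    "Encompass" means at least one resampled point lies inside the binary
    VAT; recruitment weights play no role in group assignment.
    """
    pts, offsets, _ = _sample_table(connectome, step)
    rows = []
    for vat in vats:
        inside = vat.contains(pts).astype(np.uint8)
        rows.append(np.maximum.reduceat(inside, offsets).astype(bool))
    return np.stack(rows, axis=0)


def fibre_t_scores(connectome: Connectome, vats: list[VAT], improvement,
                   top_fraction: float = DEFAULT_TOP_FRACTION,
                   min_group: int = DEFAULT_MIN_GROUP,
                   step: float = RESAMPLE_STEP_MM) -> FibreScoreResult:
    """Connected-vs-unconnected Student t per fibre, plus top-5% selection.

    Fibres are scored only when both groups have at least ``min_group``
    participants; others are reported as skipped.  Selection takes the top
    ``top_fraction`` of *positively* scoring fibres by t (rank-based, no
    p-value threshold), mirroring "fibres positively correlated with the
    primary outcome".
    """
    y = np.asarray(improvement, dtype=float)
    if len(vats) != y.shape[0]:
        raise ConnectomicsError("one VAT per participant required")
    conn = fibre_connection_matrix(connectome, vats, step)
    n_p, n_f = conn.shape
    n1 = conn.sum(axis=0).astype(float)
    n2 = n_p - n1
    sum1 = conn.T.astype(float) @ y
    sumsq1 = conn.T.astype(float) @ (y ** 2)
    tot, totsq = y.sum(), (y ** 2).sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        m1 = sum1 / n1
        m2 = (tot - sum1) / n2
        ss1 = sumsq1 - n1 * m1 ** 2
        ss2 = (totsq - sumsq1) - n2 * m2 ** 2
        sp2 = (ss1 + ss2) / (n1 + n2 - 2)
        se = np.sqrt(sp2 * (1 / n1 + 1 / n2))
        t = (m1 - m2) / se
    scored = (n1 >= min_group) & (n2 >= min_group)
    diff = m1 - m2
    # zero pooled variance: infinite separation unless the means agree too
    degen = scored & ~(sp2 > 0)
    t[degen] = np.where(diff[degen] == 0, 0.0, np.inf * np.sign(diff[degen]))
    df = n_p - 2
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p[degen & (diff != 0)] = 0.0
    t[~scored] = np.nan
    p[~scored] = np.nan

    positive = scored & (t > 0)
    n_pos = int(positive.sum())
    if scored.sum() == 0:
        warnings.warn("no scorable fibres (group sizes too small everywhere)",
                      stacklevel=2)
    if n_pos > 0:
        n_sel = max(1, int(np.ceil(top_fraction * n_pos)))
        pos_idx = np.flatnonzero(positive)
        order = pos_idx[np.argsort(-t[pos_idx], kind="stable")]
        selected = np.sort(order[:n_sel])
    else:
        selected = np.empty(0, dtype=int)
    sel_mask = np.zeros(n_f, bool)
    sel_mask[selected] = True

    table = pd.DataFrame({
        "fibre_id": np.arange(n_f),
        "bundle": (connectome.bundles if connectome.bundles is not None
                   else np.full(n_f, "")),
        "n_connected": n1.astype(int),
        "n_unconnected": n2.astype(int),
        "mean_diff": diff,
        "t": t,
        "p": p,
        "scored": scored,
        "selected": sel_mask,
    })
    return FibreScoreResult(table, selected, conn)


# ---------------------------------------------------------------------------
# ROI aggregation and association
# ---------------------------------------------------------------------------

def roi_connectivity(profile: ConnectivityProfile, parcellation: np.ndarray,
                     labels: list[int] | None = None) -> pd.Series:
    """Summed profile mass per parcellation label (background 0 excluded)."""
    parc = np.asarray(parcellation)
    if parc.shape != profile.values.shape:
        raise ConnectomicsError("parcellation must be on the profile grid")
    sums = np.bincount(parc.reshape(-1).astype(np.int64),
                       weights=profile.flat)
    present = np.flatnonzero(np.bincount(parc.reshape(-1).astype(np.int64)))
    wanted = [int(l) for l in (labels if labels is not None else present) if l != 0]
    out = {}
    for lab in wanted:
        if lab >= sums.size or lab not in present:
            warnings.warn(f"ROI label {lab} has no voxels; mass 0", stacklevel=2)
            out[lab] = 0.0
        else:
            out[lab] = float(sums[lab])
    return pd.Series(out, name="roi_mass").sort_index()


@dataclass
class RoiAssociationResult:
    multivariate: pd.DataFrame   # per-ROI time-interaction estimate, t, p
    univariate: pd.DataFrame
    dropped: list[str]
    fallback: str | None


def roi_association(roi_masses: pd.DataFrame, visits: pd.DataFrame,
                    participants: pd.DataFrame,
                    outcome: str = "ybocs") -> RoiAssociationResult:
    """Mixed-model association of ROI connectivity with outcome over time.

    ``roi_masses`` is indexed by participant_id with one column per ROI.
    Each ROI mass (z-scored across participants) enters the longitudinal
    model interacted with time-since-DBS: a negative interaction means
    stronger connectivity predicts faster score reduction.  Rank-deficient
    columns (constant, or duplicating an earlier ROI) are dropped and named.
    Univariate per-ROI fits are also reported.
    """
    if roi_masses.shape[1] < 1:
        raise ConnectomicsError("need at least one ROI column")
    df = co._prepare_longitudinal(visits, participants, outcome)

    keep, dropped = [], []
    seen: list[np.ndarray] = []
    for col in roi_masses.columns:
        v = roi_masses[col].astype(float).to_numpy()
        if np.ptp(v) == 0:
            dropped.append(str(col))
            continue
        z = (v - v.mean()) / v.std(ddof=0)
        if any(np.allclose(np.abs(np.corrcoef(z, s)[0, 1]), 1.0) for s in seen):
            dropped.append(str(col))
            continue
        seen.append(z)
        keep.append(col)
    if not keep:
        raise ConnectomicsError("all ROI columns are degenerate")

    # patsy-safe internal names; reported under the original column labels
    names = {col: f"r{k}" for k, col in enumerate(keep)}
    zmat = pd.DataFrame(
        {f"roi_{names[c]}": ((roi_masses[c] - roi_masses[c].mean())
                             / roi_masses[c].std(ddof=0))
         for c in keep},
        index=roi_masses.index,
    )
    df = df.merge(zmat, left_on="participant_id", right_index=True, how="left")
    df = df.dropna(subset=list(zmat.columns))

    base = co._fixed_formula(df, with_time=True)
    inter = " + ".join(f"time_c:roi_{names[c]}" for c in keep)
    fallback = None
    try:
        fit = co._fit_crossed(f"{base} + {inter}", df, random_slope=False)
    except Exception:
        fallback = "random intercept for participant only (crossed fit failed)"
        fit = co._fit_simple(f"{base} + {inter}", df)

    def _roi_rows(res, cols) -> pd.DataFrame:
        rows = []
        for c in cols:
            term = f"time_c:roi_{names[c]}"
            # rescale the internal per-100-day covariate to points per day
            est = float(res.fe_params[term]) / co._TIME_SCALE
            se = float(res.bse_fe[term]) / co._TIME_SCALE
            rows.append({"roi": c, "estimate": est, "se": se,
                         "t": est / se if se > 0 else np.nan,
                         "p": float(res.pvalues[term])})
        return pd.DataFrame(rows)

    multivariate = _roi_rows(fit, keep)

    uni_rows = []
    for c in keep:
        try:
            f1 = co._fit_crossed(f"{base} + time_c:roi_{names[c]}", df,
                                 random_slope=False)
        except Exception:
            f1 = co._fit_simple(f"{base} + time_c:roi_{names[c]}", df)
        uni_rows.append(_roi_rows(f1, [c]).iloc[0])
    univariate = pd.DataFrame(uni_rows).reset_index(drop=True)

    return RoiAssociationResult(multivariate, univariate, dropped, fallback)


# ---------------------------------------------------------------------------
# generic tract-recruitment replication
# ---------------------------------------------------------------------------

@dataclass
class TractRecruitmentResult:
    scores: np.ndarray   # per-participant summed recruitment weight
    r: float
    p: float


def tract_recruitment_score(tract: Connectome, efields: list[ScalarField],
                            vats: list[VAT], improvement,
                            step: float = RESAMPLE_STEP_MM) -> TractRecruitmentResult:
    """Per-participant recruitment of a named tract, correlated with outcome.

    The score is the sum over tract fibres of the E-field-normalised
    recruitment weight; the association with empirical improvement is a
    Pearson correlation.
    """
    if len(tract) == 0:
        raise ConnectomicsError("empty tract")
    y = np.asarray(improvement, dtype=float)
    if y.size < 2:
        raise ConnectomicsError("correlation undefined for fewer than 2 participants")
    if len(efields) != y.size or len(vats) != y.size:
        raise ConnectomicsError("need one field and VAT per participant")
    scores = np.array([
        recruit_fibres(tract, ef, vat, step).weights.sum()
        for ef, vat in zip(efields, vats)
    ])
    if np.ptp(scores) == 0 or np.ptp(y) == 0:
        return TractRecruitmentResult(scores, np.nan, np.nan)
    r, p = stats.pearsonr(scores, y)
    return TractRecruitmentResult(scores, float(r), float(p))
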