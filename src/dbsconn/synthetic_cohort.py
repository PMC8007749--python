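"""Phantom connectomes, electrode placements and simulated trial outcomes.

This module manufactures every input the analysis pipeline needs, with
known ground truth:

* a phantom streamline connectome on a small voxel grid, built from
  coherent fibre bundles, exactly one of which is the *response bundle*
  whose recruitment by the stimulation field drives simulated improvement;
* bilateral electrode placements, jittered around nominal targets, with
  stimulation settings drawn from the clinical protocol grid;
* longitudinal YBOCS/MADRS trajectories over a staggered-onset trial
  (recovery, randomised blinded phase, open-label phase, CBT), with the
  planted effect sizes taken from the trial this package models:
  blinded on-vs-sham difference 4.9 points, open-phase maximum reduction
  16.6 points, additive CBT effect 4.8 points, baseline YBOCS 32.7 +- 2.6.

Everything is driven by a single integer seed and is bit-for-bit
reproducible.  Noise draws are recorded in the ground truth so recovery
tests can separate estimation error from simulation noise.

The phantom emulates geometry and statistics only — there is no brain
anatomy, no diffusion signal and no imaging artefact model.  Streamline
jitter is applied per-waypoint, perpendicular to the local tangent (a
half-normal offset magnitude along a random in-plane direction), then
smoothed by spline resampling at 0.5 mm steps so bundles remain coherent
tubes rather than point clouds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy.interpolate import splev, splprep

from .connectome import Connectome
from .grids import GridSpec, resample_polyline

YBOCS_MAX = 40.0
MADRS_MAX = 60.0

#: default visit schedule: (phase, day since implantation)
DEFAULT_VISIT_SCHEDULE: tuple[tuple[str, int], ...] = (
    ("baseline", -7),
    ("recovery", 14), ("recovery", 28),
    ("blinded", 60), ("blinded", 90), ("blinded", 120),
    ("open", 150), ("open", 180), ("open", 210),
    ("open", 270), ("open", 330), ("open", 390),
    ("cbt", 450), ("post-cbt", 480),
)

PHASES = ("baseline", "recovery", "blinded", "open", "cbt", "post-cbt")

#: protocol grid for chronic stimulation settings (frequency is fixed).
#: Chronic amplitudes are individually titrated in 0.1 V steps around the
#: 4.5 V target (trial range 3.5-5.6 V); pulse width is 90 us with an
#: occasional increase to 120 us, and in about half of participants a
#: second contact is activated, mirroring the nine trial participants.
AMPLITUDE_TARGET_V = 4.5
AMPLITUDE_SD_V = 0.45
AMPLITUDE_RANGE_V = (3.5, 5.6)
PULSE_CHOICES_US = (90.0, 120.0)
PULSE_PROBS = (8 / 9, 1 / 9)
FREQ_HZ = 130.0
SECOND_CONTACT_PROB = 0.5  # five of nine trial participants


class SyntheticDataError(ValueError):
    """Invalid phantom or cohort specification."""


# ---------------------------------------------------------------------------
# phantom connectome
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BundleSpec:
    """One coherent fibre bundle: a jittered tube around a waypoint polyline."""

    name: str
    waypoints: tuple[tuple[float, float, float], ...]
    n_streamlines: int
    dispersion: float = 1.0
    is_response_bundle: bool = False

    def __post_init__(self) -> None:
        wp = np.asarray(self.waypoints, dtype=float)
        if wp.ndim != 2 or wp.shape[0] < 2 or wp.shape[1] != 3:
            raise SyntheticDataError(f"bundle {self.name!r}: need >= 2 3-D waypoints")
        if self.n_streamlines < 1:
            raise SyntheticDataError(f"bundle {self.name!r}: n_streamlines must be >= 1")
        if self.dispersion < 0:
            raise SyntheticDataError(f"bundle {self.name!r}: dispersion must be >= 0")
        object.__setattr__(self, "waypoints", tuple(tuple(p) for p in wp))


@dataclass(frozen=True)
class PhantomSpec:
    """A toy normative connectome: grid plus bundle list plus seed."""

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size: float = 1.0
    bundle_specs: tuple[BundleSpec, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if any(int(s) < 8 for s in self.grid_shape):
            raise SyntheticDataError("grid_shape entries must all be >= 8")
        if not self.voxel_size > 0:
            raise SyntheticDataError("voxel_size must be > 0")
        n_resp = sum(b.is_response_bundle for b in self.bundle_specs)
        if n_resp > 1:
            raise SyntheticDataError("at most one bundle may set is_response_bundle")
        object.__setattr__(self, "grid_shape", tuple(int(s) for s in self.grid_shape))
        object.__setattr__(self, "bundle_specs", tuple(self.bundle_specs))

    @property
    def grid(self) -> GridSpec:
        return GridSpec(self.grid_shape, self.voxel_size)


@dataclass
class Phantom:
    """Generated phantom: connectome, parcellation and bundle bookkeeping."""

    connectome: Connectome
    parcellation: np.ndarray            # integer labels on the grid
    grid: GridSpec
    label_names: dict[int, str]         # label -> "<bundle>_{start,end}"
    spec: PhantomSpec

    @property
    def response_indices(self) -> np.ndarray:
        """Streamline indices of the planted response bundle (may be empty)."""
        for b in self.spec.bundle_specs:
            if b.is_response_bundle:
                return self.connectome.bundle_indices(b.name)
        return np.empty(0, dtype=int)

    def save_parcellation(self, path: str | Path) -> None:
        img = nib.Nifti1Image(self.parcellation.astype(np.int16), self.grid.affine)
        nib.save(img, str(path))


def _perpendicular_unit(tangent: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Random unit vector in the plane perpendicular to ``tangent``."""
    for _ in range(16):
        v = rng.normal(size=3)
        v -= v.dot(tangent) * tangent
        n = np.linalg.norm(v)
        if n > 1e-8:
            return v / n
    raise RuntimeError("could not draw a perpendicular direction")  # pragma: no cover


def _waypoint_tangents(waypoints: np.ndarray) -> np.ndarray:
    diffs = np.gradient(waypoints, axis=0)
    return diffs / np.linalg.norm(diffs, axis=1, keepdims=True)


def _smooth_streamline(points: np.ndarray, step: float = 0.5) -> np.ndarray:
    """Interpolating spline through the points, resampled at ``step`` mm."""
    npts = points.shape[0]
    k = min(3, npts - 1)
    # splprep needs strictly increasing parameter; chord-length does that
    tck, _ = splprep(points.T, s=0.0, k=k)
    dense_u = np.linspace(0.0, 1.0, max(4 * npts, 50))
    dense = np.asarray(splev(dense_u, tck)).T
    return resample_polyline(dense, step)


def generate_phantom_connectome(spec: PhantomSpec) -> Phantom:
    """Build the phantom connectome and its endpoint parcellation.

    Each bundle contributes ``n_streamlines`` polylines: per-waypoint
    perpendicular jitter (half-normal magnitude, sd = ``dispersion``) around
    the centreline, spline-smoothed and resampled at 0.5 mm.  Every bundle
    endpoint is marked in the parcellation volume by a 4 mm-radius sphere
    with its own integer label (labels assigned in bundle order; later
    bundles overwrite earlier ones where spheres overlap).
    """
    grid = spec.grid
    lo, hi = grid.world_bounds
    rng = np.random.default_rng(spec.seed)
    eps = 1e-6

    streamlines: list[np.ndarray] = []
    labels: list[str] = []
    for bundle in spec.bundle_specs:
        wp = np.asarray(bundle.waypoints, dtype=float)
        if np.any(wp < lo) or np.any(wp > hi):
            raise SyntheticDataError(
                f"bundle {bundle.name!r}: waypoints outside grid world bounds"
            )
        tangents = _waypoint_tangents(wp)
        for _ in range(bundle.n_streamlines):
            jittered = wp.copy()
            if bundle.dispersion > 0:
                for j in range(wp.shape[0]):
                    mag = rng.normal(0.0, bundle.dispersion)
                    u = _perpendicular_unit(tangents[j], rng)
                    jittered[j] += mag * u
            sl = _smooth_streamline(jittered)
            np.clip(sl, lo + eps, hi - eps, out=sl)
            streamlines.append(sl)
            labels.append(bundle.name)

    parcellation = np.zeros(grid.shape, dtype=np.int16)
    label_names: dict[int, str] = {}
    centres = grid.voxel_centres()
    for b_idx, bundle in enumerate(spec.bundle_specs):
        wp = np.asarray(bundle.waypoints, dtype=float)
        for e_idx, (end, tag) in enumerate(((wp[0], "start"), (wp[-1], "end"))):
            label = 2 * b_idx + 1 + e_idx
            dist2 = np.sum((centres - end) ** 2, axis=-1)
            parcellation[dist2 <= 4.0 ** 2] = label
            label_names[label] = f"{bundle.name}_{tag}"

    connectome = Connectome(streamlines, np.asarray(labels))
    return Phantom(connectome, parcellation, grid, label_names, spec)


def default_phantom_spec(seed: int = 0, grid_shape: tuple[int, int, int] = (64, 64, 64),
                         response_standoff_mm: float = 5.5,
                         n_decoy_bundles: int = 16,
                         decoy_streamlines: int = 50) -> PhantomSpec:
    """The default study phantom.

    Straight bundles on a 64 mm cube (1 mm voxels).  The response bundle
    runs anterior-posterior ``response_standoff_mm`` lateral to the right
    stimulation target — near the edge of a protocol-amplitude VAT, so
    electrode jitter modulates both its recruitment weight and which
    participants' VATs encompass it.  A ring of decoy bundles surrounds the
    contact at varied stand-offs (3.5-5.5 mm) and orientations: their
    connection patterns are driven by other components of the placement
    jitter, giving a large, quasi-independent field of outcome-null fibres
    for the discriminative statistics to reject.  One far bundle is never
    recruited.
    """
    gx, gy, gz = grid_shape
    cx, cy, cz = gx / 2.0, gy / 2.0, gz / 2.0  # 32,32,32 on the default grid
    zc = cz - 3.25          # z of the active-contact plane (28.75 by default)
    x_right = cx + 12.0     # right target column (x = 44)

    def line(axis: str, const1: float, const2: float, lo: float, hi: float, n: int = 5):
        ts = np.linspace(lo, hi, n)
        if axis == "y":  # runs along y at (x=const1, z=const2)
            return tuple((const1, t, const2) for t in ts)
        return tuple((t, const1, const2) for t in ts)  # runs along x at (y, z)

    bundles = [
        BundleSpec("response",
                   line("y", x_right + response_standoff_mm, zc, 10.0, gy - 10.0),
                   n_streamlines=40, dispersion=1.0, is_response_bundle=True),
    ]
    # hub bundles: long fibres hugging the contact (3.2 mm stand-off) that
    # every plausible VAT recruits with near-constant weight.  They anchor
    # the field-normalisation maximum and lay a stable profile "carpet"
    # against which outcome-driven response-bundle mass can be read out by
    # the spatial-similarity predictor; being connected in everyone, they
    # are never scorable in the fibre t-test.
    for k in range(6):
        theta = 2.0 * np.pi * (k + 0.25) / 6
        if k % 2 == 0:
            wp = line("x", cy + 3.2 * np.cos(theta), zc + 3.2 * np.sin(theta),
                      6.0, gx - 6.0)
        else:
            wp = line("y", x_right + 3.2 * np.cos(theta), zc + 3.2 * np.sin(theta),
                      10.0, gy - 10.0)
        bundles.append(BundleSpec(f"hub_{k}", wp, n_streamlines=25, dispersion=0.6))
    # decoy ring: short x- and y-oriented bundles straddling the contact at
    # the VAT margin, offset from it in the plane perpendicular to their
    # course.  Their connection flips from participant to participant, so
    # they provide the dense outcome-null fibre field the discriminative
    # t-statistics must reject; keeping them short limits how much
    # outcome-irrelevant voxel mass they add to the connectivity profiles.
    radii = (4.5, 5.0, 5.5, 4.75)
    for k in range(n_decoy_bundles):
        rho = radii[k % len(radii)]
        theta = 2.0 * np.pi * (k + 0.5) / n_decoy_bundles
        if k % 2 == 0:  # runs along x, offset in (y, z) around the contact
            wp = line("x", cy + rho * np.cos(theta), zc + rho * np.sin(theta),
                      x_right - 6.0, x_right + 6.0)
        else:           # runs along y, offset in (x, z) around the contact
            wp = line("y", x_right + rho * np.cos(theta), zc + rho * np.sin(theta),
                      cy - 6.0, cy + 6.0)
        bundles.append(BundleSpec(f"decoy_{k:02d}", wp,
                                  n_streamlines=decoy_streamlines, dispersion=1.4))
    bundles.append(BundleSpec("far", line("y", cx - 22.0, cz + 18.0, 10.0, gy - 10.0),
                              n_streamlines=100, dispersion=1.0))
    return PhantomSpec(grid_shape=grid_shape, bundle_specs=tuple(bundles), seed=seed)


def default_targets(spec: PhantomSpec) -> dict[str, np.ndarray]:
    """Nominal electrode tip targets (mm) per hemisphere for a phantom grid."""
    gx, gy, gz = spec.grid_shape
    cy, cz = gy / 2.0, gz / 2.0
    return {
        "right": np.array([gx / 2.0 + 12.0, cy, cz - 6.0]) * spec.voxel_size,
        "left": np.array([gx / 2.0 - 12.0, cy, cz - 6.0]) * spec.voxel_size,
    }


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSimConfig:
    """Study conditions for the simulated trial cohort.

    Effect sizes default to the trial's reported values: baseline YBOCS
    32.7 +- 2.6, blinded on-vs-sham difference 4.9 points, open-phase
    maximum reduction 16.6 points at full recruitment, additive CBT effect
    4.8 points.  MADRS gets its own baseline and effect scale (blinded 3.4,
    open 10.8).  Electrode jitter and outcome noise are the knobs that
    control how identifiable the planted effect is.
    """

    n_participants: int = 10
    baseline_ybocs_mean: float = 32.7
    baseline_ybocs_sd: float = 2.6
    blinded_effect: float = 4.9
    open_effect_max: float = 16.6
    cbt_effect: float = 4.8
    baseline_madrs_mean: float = 25.0
    baseline_madrs_sd: float = 6.0
    madrs_blinded_effect: float = 3.4
    madrs_open_effect_max: float = 10.8
    electrode_jitter_sd: float = 1.0
    outcome_noise_sd: float = 2.0
    visit_schedule: tuple[tuple[str, int], ...] = DEFAULT_VISIT_SCHEDULE
    visit_day_jitter: int = 5
    active_onset_day: int = 30
    open_onset_day: int = 120
    cbt_start_day: int = 400
    age_mean: float = 47.9
    age_sd: float = 10.7
    female_fraction: float = 4 / 9
    withdrawn: tuple[tuple[str, int], ...] = ()  # (participant_id, day) pairs
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise SyntheticDataError("n_participants must be >= 1")
        for name in ("baseline_ybocs_sd", "baseline_madrs_sd",
                     "electrode_jitter_sd", "outcome_noise_sd", "age_sd"):
            if getattr(self, name) < 0:
                raise SyntheticDataError(f"{name} must be >= 0")
        phases = {p for p, _ in self.visit_schedule}
        bad = phases - set(PHASES)
        if bad:
            raise SyntheticDataError(f"unknown phases in visit_schedule: {sorted(bad)}")
        object.__setattr__(self, "visit_schedule",
                           tuple((str(p), int(d)) for p, d in self.visit_schedule))
        object.__setattr__(self, "withdrawn", tuple(self.withdrawn))

    def participant_ids(self) -> list[str]:
        return [f"{i + 1:02d}" for i in range(self.n_participants)]


@dataclass
class GroundTruth:
    """What the generator planted, for downstream recovery checks."""

    participant_ids: list[str]
    recruitment: np.ndarray             # per-participant weight in [0, 1]
    true_improvement_points: np.ndarray  # open-phase reduction, noise-free
    true_improvement_pct: np.ndarray
    planted_fibre_ids: np.ndarray        # indices into the phantom connectome
    ybocs_noise: np.ndarray              # (n_participants, n_visits) draws
    madrs_noise: np.ndarray

    def to_json(self, path: str | Path) -> None:
        payload = {
            "participant_ids": list(self.participant_ids),
            "recruitment": self.recruitment.tolist(),
            "true_improvement_points": self.true_improvement_points.tolist(),
            "true_improvement_pct": self.true_improvement_pct.tolist(),
            "planted_fibre_ids": self.planted_fibre_ids.tolist(),
            "ybocs_noise": self.ybocs_noise.tolist(),
            "madrs_noise": self.madrs_noise.tolist(),
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def place_electrodes(cohort: CohortSimConfig, phantom: PhantomSpec,
                     targets: dict[str, np.ndarray] | None = None) -> pd.DataFrame:
    """Bilateral electrode tips and stimulation settings for every participant.

    Tips are the nominal per-hemisphere target plus isotropic Gaussian
    jitter (sd ``electrode_jitter_sd``); a draw landing outside the grid is
    resampled (at most 100 attempts).  Settings are drawn once per
    participant from the protocol grid and applied symmetrically to both
    hemispheres, as in the trial.
    """
    if targets is None:
        targets = default_targets(phantom)
    grid = phantom.grid
    lo, hi = grid.world_bounds
    rng = np.random.default_rng(np.random.SeedSequence([cohort.seed, 11]))

    rows = []
    for pid in cohort.participant_ids():
        amp = float(np.round(np.clip(rng.normal(AMPLITUDE_TARGET_V, AMPLITUDE_SD_V),
                                     *AMPLITUDE_RANGE_V), 1))
        pw = float(rng.choice(PULSE_CHOICES_US, p=PULSE_PROBS))
        two_contacts = bool(rng.random() < SECOND_CONTACT_PROB)
        for hemi in ("right", "left"):
            target = np.asarray(targets[hemi], dtype=float)
            if np.any(target < lo) or np.any(target > hi):
                raise SyntheticDataError(f"{hemi} target outside grid bounds")
            for attempt in range(100):
                tip = target + rng.normal(0.0, cohort.electrode_jitter_sd, size=3)
                if np.all(tip > lo) and np.all(tip < hi):
                    break
            else:
                raise SyntheticDataError(
                    f"could not place {hemi} electrode for participant {pid} "
                    "inside bounds after 100 attempts"
                )
            base = 9 if hemi == "right" else 1
            contacts = [base, base + 1] if two_contacts else [base]
            rows.append({
                "participant_id": pid, "hemisphere": hemi,
                "tip_x_mm": tip[0], "tip_y_mm": tip[1], "tip_z_mm": tip[2],
                "amplitude_v": amp, "pulse_us": pw, "freq_hz": FREQ_HZ,
                "active_contacts": "-".join(str(c) for c in contacts),
            })
    return pd.DataFrame(rows)


def _accrued_effect(t_on: np.ndarray, blinded_effect: float, open_max: float) -> np.ndarray:
    """Stimulation effect as a function of days on active stimulation.

    Piecewise-linear: ramps to ``blinded_effect`` over the first 90 days
    (the blinded-phase duration), then on to ``open_max`` over the next
    160 days, then plateaus.  Both randomisation arms therefore reach the
    plateau comfortably before the scheduled CBT course and before the
    trial-exit assessment, even with per-participant visit-date jitter.
    """
    t = np.maximum(np.asarray(t_on, dtype=float), 0.0)
    first = np.minimum(t, 90.0) / 90.0 * blinded_effect
    second = np.clip(t - 90.0, 0.0, 160.0) / 160.0 * (open_max - blinded_effect)
    return first + second


def simulate_trial_timeseries(
    cohort: CohortSimConfig,
    recruitment: np.ndarray,
    planted_fibre_ids: np.ndarray | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate per-visit YBOCS/MADRS for every participant.

    ``recruitment`` is the per-participant response-bundle recruitment
    weight in [0, 1]; the accrued stimulation effect is scaled by it.  The
    sham arm accrues no effect during the blinded phase (its stimulation
    starts at ``open_onset_day``).  The CBT effect ramps in over 60 days
    from ``cbt_start_day`` for everyone still in the trial and is not
    scaled by recruitment (it is a therapy effect, not a field effect).

    Returns (visits, participants, ground_truth).  Scores are clamped to
    the instrument ranges; withdrawal is handled by carrying the last
    observed scores forward (LOCF), with an audit column ``locf``.
    """
    recruitment = np.asarray(recruitment, dtype=float)
    if recruitment.shape != (cohort.n_participants,):
        raise SyntheticDataError("recruitment must have one weight per participant")
    if np.any(recruitment < 0) or np.any(recruitment > 1):
        raise SyntheticDataError("recruitment weights must lie in [0, 1]")
    phases = [p for p, _ in cohort.visit_schedule]
    if "baseline" not in phases:
        raise SyntheticDataError("visit schedule must include a baseline visit")
    days = np.array([d for _, d in cohort.visit_schedule], dtype=float)

    rng = np.random.default_rng(np.random.SeedSequence([cohort.seed, 23]))
    ids = cohort.participant_ids()
    n, m = cohort.n_participants, len(cohort.visit_schedule)

    ages = np.clip(rng.normal(cohort.age_mean, cohort.age_sd, size=n), 18, 70)
    genders = np.where(rng.random(n) < cohort.female_fraction, "female", "male")
    n_active = (n + 1) // 2
    arm = np.array(["active"] * n_active + ["sham"] * (n - n_active))
    rng.shuffle(arm)
    base_y = np.clip(rng.normal(cohort.baseline_ybocs_mean, cohort.baseline_ybocs_sd, n),
                     0.0, YBOCS_MAX)
    base_m = np.clip(rng.normal(cohort.baseline_madrs_mean, cohort.baseline_madrs_sd, n),
                     0.0, MADRS_MAX)
    noise_y = rng.normal(0.0, cohort.outcome_noise_sd, size=(n, m))
    noise_m = rng.normal(0.0, cohort.outcome_noise_sd, size=(n, m))

    onset = np.where(arm == "active", cohort.active_onset_day, cohort.open_onset_day)
    withdrawn = dict(cohort.withdrawn)

    # Visit dates scatter per participant within scheduling windows, as in
    # a real trial; only the pre-surgical baseline is a fixed calendar
    # anchor.  The blinded-phase endpoint assessment can only be brought
    # forward (it must precede unblinding), which also keeps every
    # participant's post-operative assessment days distinct — shared
    # assessment days would let the per-timepoint random intercept of the
    # longitudinal model absorb common time trends.
    last_blinded = max((j for j, (p, _) in enumerate(cohort.visit_schedule)
                        if p == "blinded"), default=-1)

    rows = []
    is_base = np.array([p == "baseline" for p in phases])
    for i, pid in enumerate(ids):
        days_i = days.copy()
        if cohort.visit_day_jitter > 0:
            shift = rng.integers(-cohort.visit_day_jitter,
                                 cohort.visit_day_jitter + 1, size=m)
            lb_shift = int(rng.integers(-cohort.visit_day_jitter, 1))
            for j, (phase, _) in enumerate(cohort.visit_schedule):
                if is_base[j]:
                    continue
                days_i[j] = days[j] + (lb_shift if j == last_blinded
                                       else shift[j])
                if phase == "blinded":  # stay inside the blinded phase
                    days_i[j] = min(days_i[j], cohort.open_onset_day)
        t_on = days_i - onset[i]
        eff_y = _accrued_effect(t_on, cohort.blinded_effect, cohort.open_effect_max)
        eff_m = _accrued_effect(t_on, cohort.madrs_blinded_effect, cohort.madrs_open_effect_max)
        cbt = cohort.cbt_effect * np.clip((days_i - cohort.cbt_start_day) / 60.0, 0.0, 1.0)
        y = base_y[i] - eff_y * recruitment[i] - cbt + noise_y[i]
        md = base_m[i] - eff_m * recruitment[i] + noise_m[i]
        # baseline visit shows the baseline score exactly (pre-treatment rating)
        y[is_base] = base_y[i]
        md[is_base] = base_m[i]
        y = np.clip(y, 0.0, YBOCS_MAX)
        md = np.clip(md, 0.0, MADRS_MAX)
        for j, (phase, _) in enumerate(cohort.visit_schedule):
            rows.append({
                "participant_id": pid, "visit_day": int(days_i[j]), "phase": phase,
                "arm": arm[i], "ybocs": y[j], "madrs": md[j], "locf": False,
            })
    visits = pd.DataFrame(rows)

    # LOCF for withdrawn participants: carry the last pre-withdrawal scores
    for pid, wday in withdrawn.items():
        sel = visits["participant_id"] == pid
        sub = visits.loc[sel].sort_values("visit_day")
        observed = sub[sub["visit_day"] <= wday]
        if observed.empty:
            raise SyntheticDataError(f"participant {pid} withdrew before any visit")
        last = observed.iloc[-1]
        late = sel & (visits["visit_day"] > wday)
        visits.loc[late, ["ybocs", "madrs"]] = (last["ybocs"], last["madrs"])
        visits.loc[late, "locf"] = True

    participants = pd.DataFrame({
        "participant_id": ids,
        "age": ages,
        "gender": genders,
        "arm": arm,
        "baseline_ybocs": base_y,
        "baseline_madrs": base_m,
        "withdrawn_at": [withdrawn.get(pid, np.nan) for pid in ids],
    })

    true_points = cohort.open_effect_max * recruitment
    truth = GroundTruth(
        participant_ids=ids,
        recruitment=recruitment,
        true_improvement_points=true_points,
        true_improvement_pct=100.0 * true_points / base_y,
        planted_fibre_ids=(np.empty(0, dtype=int) if planted_fibre_ids is None
                           else np.asarray(planted_fibre_ids, dtype=int)),
        ybocs_noise=noise_y,
        madrs_noise=noise_m,
    )
    return visits, participants, truth


def improvement_percent(visits: pd.DataFrame, outcome: str = "ybocs",
                        phase: str = "open") -> pd.Series:
    """Per-participant % reduction from baseline to the last visit of ``phase``."""
    col = outcome
    out = {}
    for pid, sub in visits.groupby("participant_id"):
        sub = sub.sort_values("visit_day")
        base = sub.loc[sub["phase"] == "baseline", col]
        end = sub.loc[sub["phase"] == phase, col]
        if base.empty or end.empty:
            raise SyntheticDataError(f"participant {pid}: missing baseline or {phase} visit")
        b = float(base.iloc[0])
        if b == 0:
            raise SyntheticDataError(f"participant {pid}: zero baseline score")
        out[pid] = 100.0 * (b - float(end.iloc[-1])) / b
    return pd.Series(out, name=f"{outcome}_pct_reduction").sort_index()
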