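"""End-to-end validation experiments on the synthetic study.

These are the package's own Monte-Carlo checks that the full analysis chain
recovers what the generator plants, and that its test statistics are
calibrated when nothing is planted.  They are used both by the test suite
and by the reproduction script.

All experiments derive their per-cohort seeds from one base seed via
``numpy.random.SeedSequence`` so a single integer reproduces everything.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import clinical_outcomes as co
from . import fibre_connectomics as fc
from .pipeline import synthesise_cohort, _electrode_from_row
from .stimulation_model import (
    ElectrodeModel, StimulationSetting, simulate_efield, threshold_vat,
)
from .grids import GridSpec
from .synthetic_cohort import (
    CohortSimConfig, default_phantom_spec, generate_phantom_connectome,
    place_electrodes, simulate_trial_timeseries,
)


def _spawn_seeds(base_seed: int, n: int) -> np.ndarray:
    """n reproducible 31-bit cohort seeds from one base seed."""
    return np.random.SeedSequence(base_seed).generate_state(n) % (2 ** 31)


# ---------------------------------------------------------------------------
# VAT analytics
# ---------------------------------------------------------------------------

def vat_sphere_check(amplitude: float = 4.5, ke: float = 1.0,
                     et90: float = 0.2) -> dict:
    """Single-contact VAT volume vs the closed-form sphere.

    The super-threshold region of a capped inverse-square point source is a
    sphere of radius sqrt(ke * V / E_t); the voxel-counted volume should
    agree with (4/3) pi r^3 to within discretisation error.
    """
    grid = GridSpec((40, 40, 40), voxel_size=1.0)
    electrode = ElectrodeModel(tip=(20.0, 20.0, 14.0), hemisphere="right")
    setting = StimulationSetting((9,), amplitude)
    field = simulate_efield(electrode, setting, grid, ke=ke)
    vat = threshold_vat(field, setting, et90=et90)
    r = np.sqrt(ke * amplitude / et90)
    sphere = 4.0 / 3.0 * np.pi * r ** 3
    return {
        "vat_volume_mm3": vat.volume_mm3,
        "sphere_volume_mm3": float(sphere),
        "pct_error": 100.0 * abs(vat.volume_mm3 - sphere) / sphere,
    }


# ---------------------------------------------------------------------------
# planted-effect recovery
# ---------------------------------------------------------------------------

@dataclass
class RecoveryResult:
    dice: np.ndarray                 # per-cohort Dice of top-5% set vs bundle
    loocv_r: np.ndarray              # per-cohort observed LOOCV correlation
    loocv_null: np.ndarray           # (n_cohorts, n_permutations) null r
    identifiability: np.ndarray      # per-cohort Spearman(recruitment, improvement)

    @property
    def median_dice(self) -> float:
        return float(np.median(self.dice))

    @property
    def median_loocv_r(self) -> float:
        return float(np.nanmedian(self.loocv_r))

    @property
    def loocv_median_null_95(self) -> float:
        """95th percentile of the permutation distribution of the
        median-over-cohorts LOOCV correlation (permutations aligned across
        cohorts)."""
        med = np.nanmedian(self.loocv_null, axis=0)
        return float(np.nanpercentile(med, 95))


def planted_effect_recovery(n_cohorts: int = 20, n_permutations: int = 100,
                            base_seed: int = 1) -> RecoveryResult:
    """Run the full chain on default synthetic cohorts and score recovery.

    Per cohort: Dice overlap between the selected top-5% fibre set and the
    planted response bundle, and the LOOCV predicted-vs-empirical Pearson r
    with its permutation null.  The significance of the LOOCV association
    across the experiment is judged at the ensemble level: the median
    observed r over cohorts against the 95th percentile of the permutation
    distribution of that median.
    """
    seeds = _spawn_seeds(base_seed, n_cohorts)
    dice, robs, idents, nulls = [], [], [], []
    for seed in seeds:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            syn = synthesise_cohort(seed=int(seed))
            improvement = syn.improvement()
            profiles = syn.profiles()
            r, null, _ = fc.loocv_permutation_test(
                profiles, improvement, n_permutations=n_permutations,
                seed=int(seed))
            scores = fc.fibre_t_scores(syn.phantom.connectome,
                                       syn.hemisphere_vats(), improvement)
        planted = set(syn.phantom.response_indices.tolist())
        selected = set(scores.selected.tolist())
        denom = len(planted) + len(selected)
        dice.append(2 * len(planted & selected) / denom if denom else 0.0)
        robs.append(r)
        nulls.append(null)
        idents.append(stats.spearmanr(syn.ground_truth.recruitment,
                                      improvement)[0])
    return RecoveryResult(np.asarray(dice), np.asarray(robs),
                          np.asarray(nulls), np.asarray(idents))


# ---------------------------------------------------------------------------
# null calibration
# ---------------------------------------------------------------------------

def lmm_null_calibration(n_cohorts: int = 100, base_seed: int = 2) -> dict:
    """LRT p of the time effect across cohorts with no planted improvement."""
    ps = []
    for seed in _spawn_seeds(base_seed, n_cohorts):
        cfg = CohortSimConfig(seed=int(seed), cbt_effect=0.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            visits, participants, _ = simulate_trial_timeseries(
                cfg, np.zeros(cfg.n_participants))
            res = co.longitudinal_mixed_model(visits, participants)
        ps.append(res.lrt_p)
    ps = np.asarray(ps)
    return {"p_values": ps,
            "ks_p": float(stats.kstest(ps, "uniform").pvalue),
            "frac_below_05": float((ps < 0.05).mean())}


def connectomics_null_calibration(n_cohorts: int = 100, base_seed: int = 3,
                                  n_permutations: int = 49) -> dict:
    """Fibre-level t-test p and LOOCV permutation p under outcome-null data.

    The phantom is generated once; each cohort draws fresh electrode
    placements and an improvement vector unrelated to any fibre.
    """
    phantom = generate_phantom_connectome(default_phantom_spec(seed=0))
    fibre_ps, loocv_ps = [], []
    for seed in _spawn_seeds(base_seed, n_cohorts):
        cfg = CohortSimConfig(seed=int(seed))
        rng = np.random.default_rng(int(seed))
        electrodes = place_electrodes(cfg, phantom.spec)
        vats, profiles = [], []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for pid in cfg.participant_ids():
                row = electrodes[(electrodes.participant_id == pid)
                                 & (electrodes.hemisphere == "right")].iloc[0]
                electrode, setting = _electrode_from_row(row)
                field = simulate_efield(electrode, setting, phantom.grid)
                vat = threshold_vat(field, setting)
                vats.append(vat)
                w = fc.recruit_fibres(phantom.connectome, field, vat)
                profiles.append(fc.connectivity_profile(
                    w, phantom.connectome, phantom.grid))
            improvement = rng.normal(50.0, 10.0, cfg.n_participants)
            scores = fc.fibre_t_scores(phantom.connectome, vats, improvement)
            scorable = scores.table[scores.table.scored]
            if len(scorable):
                fibre_ps.append(float(scorable.p.iloc[0]))
            _, _, p = fc.loocv_permutation_test(
                profiles, improvement, n_permutations=n_permutations,
                seed=int(seed))
            loocv_ps.append(p)
    fibre_ps = np.asarray(fibre_ps)
    loocv_ps = np.asarray(loocv_ps)
    return {
        "fibre_p_values": fibre_ps,
        "fibre_ks_p": float(stats.kstest(fibre_ps, "uniform").pvalue),
        "loocv_p_values": loocv_ps,
        "loocv_ks_p": float(stats.kstest(loocv_ps, "uniform").pvalue),
    }


# ---------------------------------------------------------------------------
# mixed-model slope recovery
# ---------------------------------------------------------------------------

def lmm_slope_recovery(n_cohorts: int = 100, slope: float = -0.03,
                       noise_sd: float = 2.0, n_participants: int = 9,
                       base_seed: int = 4) -> dict:
    """Recover a planted linear time slope (points/day) with the mixed model."""
    days = [14, 28, 60, 90, 120, 150, 180, 210, 270, 330, 390]
    estimates = []
    for seed in _spawn_seeds(base_seed, n_cohorts):
        rng = np.random.default_rng(int(seed))
        rows, parts = [], []
        for i in range(n_participants):
            pid = f"{i + 1:02d}"
            base = float(np.clip(rng.normal(32.7, 2.6), 0, 40))
            intercept = rng.normal(0, 1.5)
            parts.append(dict(
                participant_id=pid, age=float(rng.normal(47.9, 10.7)),
                gender="female" if rng.random() < 0.45 else "male",
                arm="active", baseline_ybocs=base, baseline_madrs=20.0,
                withdrawn_at=np.nan))
            for d in days:
                rows.append(dict(
                    participant_id=pid, visit_day=d,
                    phase="open" if d > 120 else "blinded", arm="active",
                    ybocs=base + intercept + slope * d + rng.normal(0, noise_sd),
                    madrs=20.0, locf=False))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = co.longitudinal_mixed_model(pd.DataFrame(rows),
                                              pd.DataFrame(parts))
        estimates.append(res.time_coefficient)
    estimates = np.asarray(estimates)
    bias_pct = 100.0 * abs(estimates.mean() - slope) / abs(slope)
    return {"planted_slope": slope, "mean_estimate": float(estimates.mean()),
            "bias_pct": float(bias_pct), "estimates": estimates}
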