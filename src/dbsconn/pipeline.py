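"""End-to-end orchestration: synthesise, stimulate, score, associate, report.

Also houses the packaged nine-participant endpoint fixture (baseline YBOCS
and printed percentage reductions at the end of the open phase) used by the
deterministic cohort statistics, and the run manifest machinery that makes
pipeline outputs reproducible and hashable.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import clinical_outcomes as co
from . import fibre_connectomics as fc
from .connectome import Connectome
from .grids import GridSpec
from .stimulation_model import (
    ElectrodeModel, StimulationSetting, ScalarField, VAT,
    simulate_efield, threshold_vat, DEFAULT_KE, DEFAULT_ET90,
)
from .synthetic_cohort import (
    CohortSimConfig, Phantom, PhantomSpec,
    default_phantom_spec, default_targets, generate_phantom_connectome,
    improvement_percent, place_electrodes, simulate_trial_timeseries,
)


class ConfigError(ValueError):
    """Invalid or incomplete run configuration."""




# ---------------------------------------------------------------------------
# packaged trial endpoint fixture
# ---------------------------------------------------------------------------

#: Nine-participant endpoint table: demographics, baseline YBOCS, printed
#: percentage reductions at the end of the open phase, and the chronic
#: right/left stimulation settings (case-positive monopolar).
_TABLE1 = {
    "participant_id": ["01", "02", "03", "04", "05", "06", "07", "08", "09"],
    "age": [28, 29, 57, 54, 57, 47, 54, 48, 55],
    "gender": ["female", "male", "male", "male", "female",
               "female", "male", "female", "male"],
    "baseline_ybocs": [32, 33, 29, 35, 32, 28, 35, 34, 36],
    "ybocs_pct_reduction": [53.1, 69.7, 51.7, 54.3, 28.1, 0.0, 48.6, 82.3, 58.3],
    "madrs_pct_reduction": [57.1, 70.6, 50.0, 35.3, 46.2, -4.0, 80.0, 78.9, 77.8],
    "right_contacts": ["8-9", "9", "9", "9-10", "9", "10", "9-10", "9-10", "9-10"],
    "left_contacts": ["0-1", "1", "1", "1-2", "1", "1", "1-2", "1-2", "1-2"],
    "amplitude_v": [4.5, 3.5, 4.5, 4.7, 4.5, 5.6, 4.5, 4.5, 5.0],
    "pulse_us": [90, 90, 90, 90, 90, 120, 90, 90, 90],
    "freq_hz": [130] * 9,
}


def make_table1_fixture(outdir: str | Path | None = None
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """The packaged nine-participant fixture.

    Returns (participants, endpoints): demographics plus stimulation
    settings, and per-participant percentage reductions with the YBOCS
    endpoint back-computed from baseline x (1 - reduction/100).  If
    ``outdir`` is given, both tables are written as CSV.
    """
    df = pd.DataFrame(_TABLE1)
    participants = df[["participant_id", "age", "gender", "baseline_ybocs",
                       "right_contacts", "left_contacts", "amplitude_v",
                       "pulse_us", "freq_hz"]].copy()
    endpoints = df[["participant_id", "baseline_ybocs",
                    "ybocs_pct_reduction", "madrs_pct_reduction"]].copy()
    endpoints["ybocs_endpoint"] = (
        endpoints["baseline_ybocs"] * (1 - endpoints["ybocs_pct_reduction"] / 100.0)
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        participants.to_csv(outdir / "table1_participants.csv", index=False)
        endpoints.to_csv(outdir / "table1_endpoints.csv", index=False)
    return participants, endpoints


def table1_statistics() -> dict[str, float]:
    """Deterministic cohort statistics from the packaged endpoint fixture."""
    _, endpoints = make_table1_fixture()
    ybocs_pct = endpoints["ybocs_pct_reduction"].to_numpy()
    madrs_pct = endpoints["madrs_pct_reduction"].to_numpy()
    base = endpoints["baseline_ybocs"].to_numpy(dtype=float)

    y_sum = co.cohort_summary(ybocs_pct)
    m_sum = co.cohort_summary(madrs_pct)
    b_sum = co.cohort_summary(base)
    abs_red = co.cohort_summary(base * ybocs_pct / 100.0)
    _, n_resp_y = co.classify_responders(ybocs_pct, 35.0)
    _, n_resp_m = co.classify_responders(madrs_pct, 50.0)
    return {
        "ybocs_pct_reduction_mean": y_sum.mean,
        "ybocs_pct_reduction_sd": y_sum.sd,
        "madrs_pct_reduction_mean": m_sum.mean,
        "madrs_pct_reduction_sd": m_sum.sd,
        "baseline_ybocs_mean": b_sum.mean,
        "baseline_ybocs_sd_pop": b_sum.sd_pop,
        "ybocs_abs_reduction_mean": abs_red.mean,
        "ybocs_responders": float(n_resp_y),
        "madrs_responders": float(n_resp_m),
        "n": float(len(endpoints)),
    }


# ---------------------------------------------------------------------------
# synthetic cohort orchestration
# ---------------------------------------------------------------------------

def _electrode_from_row(row: pd.Series) -> tuple[ElectrodeModel, StimulationSetting]:
    electrode = ElectrodeModel(
        tip=(row["tip_x_mm"], row["tip_y_mm"], row["tip_z_mm"]),
        direction=(0.0, 0.0, 1.0),
        hemisphere=row["hemisphere"],
    )
    contacts = tuple(int(c) for c in str(row["active_contacts"]).split("-"))
    setting = StimulationSetting(contacts, float(row["amplitude_v"]),
                                 float(row["pulse_us"]), float(row["freq_hz"]))
    return electrode, setting


@dataclass
class SyntheticCohort:
    """A fully materialised synthetic study: inputs, fields and outcomes."""

    phantom: Phantom
    electrodes: pd.DataFrame
    efields: dict[tuple[str, str], ScalarField]     # (participant, hemisphere)
    vats: dict[tuple[str, str], VAT]
    recruitment: dict[tuple[str, str], fc.RecruitmentWeights]
    visits: pd.DataFrame
    participants: pd.DataFrame
    ground_truth: "object"
    cohort_config: CohortSimConfig

    def participant_ids(self) -> list[str]:
        return list(self.cohort_config.participant_ids())

    def hemisphere_vats(self, hemisphere: str = "right") -> list[VAT]:
        return [self.vats[(pid, hemisphere)] for pid in self.participant_ids()]

    def hemisphere_efields(self, hemisphere: str = "right") -> list[ScalarField]:
        return [self.efields[(pid, hemisphere)] for pid in self.participant_ids()]

    def profiles(self, hemisphere: str = "right") -> list[fc.ConnectivityProfile]:
        out = []
        for pid in self.participant_ids():
            w = self.recruitment[(pid, hemisphere)]
            out.append(fc.connectivity_profile(
                w, self.phantom.connectome, self.phantom.grid,
                participant_id=pid, hemisphere=hemisphere))
        return out

    def improvement(self, outcome: str = "ybocs") -> np.ndarray:
        return improvement_percent(self.visits, outcome).to_numpy()


def synthesise_cohort(cohort: CohortSimConfig | None = None,
                      phantom_spec: PhantomSpec | None = None,
                      ke: float = DEFAULT_KE, et90: float = DEFAULT_ET90,
                      margin_mm: float = 10.0,
                      seed: int | None = None) -> SyntheticCohort:
    """Generate the full study: phantom, electrodes, fields, outcomes.

    Each participant's ground-truth recruitment is the fraction of the
    planted response bundle's fibres encompassed by their *right*-hemisphere
    VAT (the response bundle sits in the right hemisphere), which then
    drives the simulated YBOCS/MADRS trajectories.
    """
    if seed is not None:
        cohort = (cohort or CohortSimConfig())
        cohort = CohortSimConfig(**{**asdict(cohort), "seed": seed})
    cohort = cohort or CohortSimConfig()
    phantom_spec = phantom_spec or default_phantom_spec(seed=cohort.seed)
    phantom = generate_phantom_connectome(phantom_spec)
    electrodes = place_electrodes(cohort, phantom_spec)

    efields: dict[tuple[str, str], ScalarField] = {}
    vats: dict[tuple[str, str], VAT] = {}
    recruitment: dict[tuple[str, str], fc.RecruitmentWeights] = {}
    for _, row in electrodes.iterrows():
        key = (row["participant_id"], row["hemisphere"])
        electrode, setting = _electrode_from_row(row)
        ef = simulate_efield(electrode, setting, phantom.grid, ke=ke,
                             margin_mm=margin_mm)
        vat = threshold_vat(ef, setting, et90=et90)
        efields[key] = ef
        vats[key] = vat
        recruitment[key] = fc.recruit_fibres(phantom.connectome, ef, vat)

    resp = phantom.response_indices
    fractions = []
    for pid in cohort.participant_ids():
        w = recruitment[(pid, "right")].weights
        # weight > 0 iff the fibre has at least one sample inside the VAT
        fractions.append(float((w[resp] > 0).mean()) if resp.size else 0.0)
    truth_recruitment = np.clip(np.asarray(fractions), 0.0, 1.0)

    visits, participants, truth = simulate_trial_timeseries(
        cohort, truth_recruitment, planted_fibre_ids=resp)
    return SyntheticCohort(phantom, electrodes, efields, vats, recruitment,
                           visits, participants, truth, cohort)


def rank_rois_by_rmap(rmap: "fc.RMap", parcellation: np.ndarray,
                      label_names: dict[int, str] | None = None) -> list:
    """Parcellation labels ranked by mean valid R-map rho (descending).

    Mirrors selecting the regions a cohort R-map implicates before entering
    them into the ROI mixed model.  Labels without any valid R-map voxel
    rank last.
    """
    rho = rmap.rho.reshape(-1)
    valid = rmap.valid.reshape(-1)
    flat = np.asarray(parcellation).reshape(-1).astype(np.int64)
    scores = {}
    for lab in np.unique(flat):
        if lab == 0:
            continue
        sel = (flat == lab) & valid
        scores[int(lab)] = float(np.nanmean(rho[sel])) if sel.any() else -np.inf
    order = sorted(scores, key=scores.get, reverse=True)
    if label_names:
        return [label_names.get(l, str(l)) for l in order]
    return order


# ---------------------------------------------------------------------------
# run configuration and manifest
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """One YAML-serialisable pipeline configuration."""

    seed: int = 0
    outdir: str = "dbsconn_run"
    synth: dict | None = field(default_factory=dict)  # phantom/cohort overrides
    inputs: dict | None = None                        # paths to external inputs
    params: dict = field(default_factory=dict)        # analysis knobs

    REQUIRED_INPUTS = ("connectome", "electrodes", "visits", "participants")

    def validate(self) -> None:
        if self.synth is None and self.inputs is None:
            raise ConfigError("config needs either a 'synth' block or an 'inputs' block")
        if self.synth is None:
            for key in self.REQUIRED_INPUTS:
                if key not in self.inputs:
                    raise ConfigError(f"missing required field: inputs.{key}")
                if not Path(self.inputs[key]).exists():
                    raise ConfigError(f"inputs.{key}: path does not exist: "
                                      f"{self.inputs[key]}")

    # -- YAML round trip --------------------------------------------------

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        allowed = {"seed", "outdir", "synth", "inputs", "params"}
        unknown = set(data) - allowed
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        return cls(**data)

    def config_hash(self) -> str:
        """Hash of the scientific configuration (output location excluded)."""
        payload = {k: v for k, v in asdict(self).items() if k != "outdir"}
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _meta_line(config: RunConfig) -> str:
    return f"# dbsconn {__version__} seed={config.seed} config={config.config_hash()}"


def _write_csv(df: pd.DataFrame, path: Path, config: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write(_meta_line(config) + "\n")
        df.to_csv(fh, index=False)


def read_artefact_csv(path: str | Path) -> pd.DataFrame:
    """Read a pipeline CSV, skipping the embedded metadata comment line."""
    return pd.read_csv(path, comment="#")


def _write_json(obj: dict, path: Path, config: RunConfig) -> None:
    obj = {"_meta": {"version": __version__, "seed": config.seed,
                     "config": config.config_hash()}, **obj}
    path.write_text(json.dumps(obj, indent=1, sort_keys=True, default=float))


def _nifti_with_meta(data: np.ndarray, affine: np.ndarray,
                     config: RunConfig) -> nib.Nifti1Image:
    img = nib.Nifti1Image(data, affine)
    img.header["descrip"] = _meta_line(config)[2:79].encode()
    return img


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages in dependency order and write a hashed manifest.

    Stages: synth -> vat -> recruit -> rmap -> loocv -> fibrescore -> roi ->
    outcomes.  A stage failure marks everything downstream as skipped and
    raises after the manifest is written.  With a fixed seed, rerunning
    reproduces identical artefact hashes for all deterministic stages.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = dict(config.params or {})
    ke = float(params.get("ke", DEFAULT_KE))
    et90 = float(params.get("et90", DEFAULT_ET90))
    hemisphere = str(params.get("hemisphere", "right"))
    top_fraction = float(params.get("top_fraction", fc.DEFAULT_TOP_FRACTION))
    n_perm = int(params.get("n_permutations", 100))
    responder_threshold = float(params.get("responder_threshold", 35.0))

    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "stages": [],
    }
    stage_order = ["synth", "vat", "recruit", "rmap", "loocv",
                   "fibrescore", "roi", "outcomes"]
    done: list[str] = []

    def record(stage: str, artefacts: list[Path]) -> None:
        manifest["stages"].append({
            "name": stage, "status": "complete",
            "artefacts": [{"path": str(p.relative_to(outdir)), "sha256": _sha256(p)}
                          for p in artefacts],
        })
        done.append(stage)

    def finish(error: str | None = None) -> dict:
        for stage in stage_order:
            if stage not in done:
                manifest["stages"].append({
                    "name": stage,
                    "status": "failed" if error and stage == failed_stage else "skipped",
                    "artefacts": [],
                })
        if error:
            manifest["error"] = error
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=1, sort_keys=True))
        return manifest

    failed_stage = None
    try:
        # ---- synth ------------------------------------------------------
        failed_stage = "synth"
        phantom_block = (config.synth or {}).get("phantom")
        if phantom_block:
            phantom_block = dict(phantom_block)
            if "bundle_specs" in phantom_block:
                from .synthetic_cohort import BundleSpec
                phantom_block["bundle_specs"] = tuple(
                    b if isinstance(b, BundleSpec) else BundleSpec(**b)
                    for b in phantom_block["bundle_specs"])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            syn = synthesise_cohort(
                cohort=CohortSimConfig(**{**(config.synth or {}).get("cohort", {}),
                                          "seed": config.seed}),
                phantom_spec=None if not phantom_block
                else PhantomSpec(**phantom_block),
                ke=ke, et90=et90)
        arts = []
        p = outdir / "connectome.tck"
        syn.phantom.connectome.save(p)
        arts.append(p)
        p = outdir / "parcellation.nii"
        nib.save(_nifti_with_meta(syn.phantom.parcellation.astype(np.int16),
                                  syn.phantom.grid.affine, config), p)
        arts.append(p)
        for name, df in (("electrodes", syn.electrodes), ("visits", syn.visits),
                         ("participants", syn.participants)):
            p = outdir / f"{name}.csv"
            _write_csv(df, p, config)
            arts.append(p)
        p = outdir / "ground_truth.json"
        syn.ground_truth.to_json(p)
        arts.append(p)
        record("synth", arts)

        # ---- vat --------------------------------------------------------
        failed_stage = "vat"
        arts = []
        for (pid, hemi), vat in sorted(syn.vats.items()):
            p = outdir / f"vat_{pid}_{hemi}.nii"
            nib.save(_nifti_with_meta(vat.mask.astype(np.uint8),
                                      vat.grid.affine, config), p)
            arts.append(p)
        record("vat", arts)

        # ---- recruit ----------------------------------------------------
        failed_stage = "recruit"
        profiles = syn.profiles(hemisphere)
        improvement = syn.improvement("ybocs")
        rows = []
        for pid, prof in zip(syn.participant_ids(), profiles):
            w = syn.recruitment[(pid, hemisphere)].weights
            rows.append({"participant_id": pid, "hemisphere": hemisphere,
                         "n_recruited": int((w > 0).sum()),
                         "total_weight": float(w.sum()),
                         "profile_mass": float(prof.flat.sum())})
        p = outdir / "recruitment.csv"
        _write_csv(pd.DataFrame(rows), p, config)
        record("recruit", [p])

        # ---- rmap -------------------------------------------------------
        failed_stage = "rmap"
        rmap = fc.compute_rmap(profiles, improvement)
        p = outdir / "rmap.nii"
        nib.save(_nifti_with_meta(rmap.rho.astype(np.float32),
                                  rmap.grid.affine, config), p)
        record("rmap", [p])

        # ---- loocv ------------------------------------------------------
        failed_stage = "loocv"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            loocv = fc.loocv_predict(profiles, improvement)
            obs_r, _, perm_p = fc.loocv_permutation_test(
                profiles, improvement, n_permutations=n_perm, seed=config.seed)
        p = outdir / "loocv.json"
        _write_json({
            "pearson_r": loocv.pearson_r, "pearson_p": loocv.pearson_p,
            "spearman_r": loocv.spearman_r, "spearman_p": loocv.spearman_p,
            "permutation_p": perm_p,
            "predictions": [None if not np.isfinite(v) else float(v)
                            for v in loocv.predictions],
        }, p, config)
        record("loocv", [p])

        # ---- fibrescore -------------------------------------------------
        failed_stage = "fibrescore"
        scores = fc.fibre_t_scores(syn.phantom.connectome,
                                   syn.hemisphere_vats(hemisphere),
                                   improvement, top_fraction=top_fraction)
        p = outdir / "fibre_scores.csv"
        _write_csv(scores.table, p, config)
        arts = [p]
        if scores.selected.size:
            p = outdir / "selected_fibres.tck"
            syn.phantom.connectome.subset(scores.selected).save(p)
            arts.append(p)
        record("fibrescore", arts)

        # ---- roi --------------------------------------------------------
        failed_stage = "roi"
        roi_rows = {}
        for pid, prof in zip(syn.participant_ids(), profiles):
            roi_rows[pid] = fc.roi_connectivity(prof, syn.phantom.parcellation)
        roi_masses = pd.DataFrame(roi_rows).T
        roi_masses.columns = [syn.phantom.label_names.get(int(c), str(c))
                              for c in roi_masses.columns]
        # as in the source analysis, the regions entered into the model are
        # the ones the R-map implicates: rank labels by mean valid rho
        n_roi = int(params.get("n_roi", 6))
        roi_masses = roi_masses[rank_rois_by_rmap(
            rmap, syn.phantom.parcellation, syn.phantom.label_names)[:n_roi]]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            roi_res = fc.roi_association(roi_masses, syn.visits, syn.participants)
        p = outdir / "roi_association.csv"
        _write_csv(roi_res.multivariate, p, config)
        p2 = outdir / "roi_univariate.csv"
        _write_csv(roi_res.univariate, p2, config)
        record("roi", [p, p2])

        # ---- outcomes ---------------------------------------------------
        failed_stage = "outcomes"
        act, sham = co.blinded_changes(syn.visits)
        blinded = co.blinded_phase_comparison(act, sham)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            lmm = co.longitudinal_mixed_model(syn.visits, syn.participants)
            cbt = co.cbt_effect(syn.visits)
        _, n_resp = co.classify_responders(improvement, responder_threshold)
        summary = co.cohort_summary(improvement)
        p = outdir / "outcomes.json"
        _write_json({
            "blinded_t": blinded.t, "blinded_p": blinded.p,
            "blinded_mean_difference": blinded.mean_diff,
            "lmm_time_coefficient": lmm.time_coefficient,
            "lmm_lrt_chi2": lmm.lrt_chi2, "lmm_lrt_p": lmm.lrt_p,
            "cbt_mean_difference": cbt.mean_diff, "cbt_p": cbt.p,
            "responders": n_resp,
            "pct_reduction_mean": summary.mean, "pct_reduction_sd": summary.sd,
        }, p, config)
        record("outcomes", [p])
        failed_stage = None
    except Exception as exc:  # manifest must record the failure
        finish(f"{failed_stage}: {exc}")
        raise
    return finish()
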