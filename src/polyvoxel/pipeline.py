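"""End-to-end pipeline: simulate -> cohort -> fit -> score -> importance ->
iron -> risk -> replicate, with a manifest sufficient to re-run
bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import importance as imp
from . import iron as iron_mod
from . import replication as rep
from .cohort import match_controls, split_samples
from .datatypes import ConfigurationError, subsample_c_mask
from .pvs import DEFAULT_R_GRID, crossval_select_r, fit_pvs, score_images
from .risk import estimate_ipw, quantile_risk, weighted_logistic
from .synthetic import GeneratorConfig, simulate_all

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger("polyvoxel")


@dataclass
class RunConfig:
    """Parameters for one full run; serializes losslessly to/from YAML."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    match_ratio: int = 4
    r: int | str = "cv"  # integer rank, or "cv" for cross-validated choice
    grid: tuple = DEFAULT_R_GRID
    folds: int = 5
    p_thresh: float = 0.01
    outcome: str = "dx_disease"
    discovery_fraction: float = 0.75
    selection_p: float = 1e-3
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        gen_raw = raw.pop("generator", {})
        gen_known = {f.name for f in dataclasses.fields(GeneratorConfig)}
        gen_unknown = set(gen_raw) - gen_known
        if gen_unknown:
            raise ConfigurationError(f"unknown generator keys: {sorted(gen_unknown)}")
        for key in ("covariate_effects", "risk_params", "age_range"):
            if key in gen_raw:
                gen_raw[key] = tuple(gen_raw[key])
        if "grid" in raw:
            raw["grid"] = tuple(raw["grid"])
        return cls(generator=GeneratorConfig(**gen_raw), **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _write(df: pd.DataFrame, path: Path, cfg_hash: str) -> str:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={cfg_hash}\n")
        df.to_csv(fh, sep="\t", index=False, na_rep="NA")
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Execute every stage on a simulated study; returns the manifest dict.

    Artifacts (all TSV/JSON, each stamped with the config hash) land in
    ``out_dir``; the manifest records inputs, seeds and output hashes.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.config_hash()
    manifest = {"config": config.to_dict(), "config_hash": cfg_hash, "outputs": {}}

    def stage(name):
        log.info("stage: %s", name)

    stage("simulate")
    study = simulate_all(config.generator)
    subjects, truth = study.subjects, study.truth

    stage("build-cohort")
    matched = match_controls(subjects, ratio=config.match_ratio, seed=config.seed)
    subjects = split_samples(subjects, matched)
    manifest["outputs"]["subjects"] = _write(
        subjects, out_dir / "subjects.tsv", cfg_hash
    )

    a_mask = subjects["subsample"] == "A"
    a_ids = subjects.loc[a_mask, "subject_id"]
    t2w_a = study.t2w.select_subjects(a_ids)
    table_a = subjects.loc[a_mask].reset_index(drop=True)
    y_a = (table_a["genotype_class"] == "homozygote").to_numpy(int)

    if config.r == "cv":
        stage("crossval")
        cv = crossval_select_r(
            t2w_a.data, table_a, y_a, grid=config.grid,
            k=config.folds, seed=config.seed, p_thresh=config.p_thresh,
        )
        r = cv.selected_r
        manifest["cv"] = {
            "selected_r": int(r),
            "fold_optima": cv.fold_optima.tolist(),
            "mean_auc_by_grid": cv.auc.mean(axis=0).tolist(),
        }
    else:
        r = int(config.r)

    stage("fit")
    model = fit_pvs(t2w_a, table_a, y_a, r=r, p_thresh=config.p_thresh, seed=config.seed)
    model.save(out_dir / "model.pvs.npz")
    manifest["outputs"]["model"] = hashlib.sha256(
        (out_dir / "model.pvs.npz").read_bytes()
    ).hexdigest()[:16]
    manifest["model"] = {"r": int(r), "n_retained": int(len(model.retained_idx))}

    stage("score")
    b_mask = subjects["subsample"] == "B"
    table_b = subjects.loc[b_mask].reset_index(drop=True)
    t2w_b = study.t2w.select_subjects(table_b["subject_id"])
    pvs_b = score_images(model, t2w_b, table_b)
    scores = pd.DataFrame({"subject_id": table_b["subject_id"], "pvs": pvs_b})
    manifest["outputs"]["scores"] = _write(scores, out_dir / "scores.tsv", cfg_hash)

    stage("importance")
    atlas_retained = type(study.atlas)(
        labels=study.atlas.labels[model.retained_idx], names=study.atlas.names
    )
    t2star_b = study.t2star.select_subjects(table_b["subject_id"])
    t2star_b_retained = type(t2star_b)(
        t2star_b.data[:, model.retained_idx],
        t2star_b.subject_ids,
        "T2star",
        np.ones((len(model.retained_idx), 1, 1), dtype=bool),
    )
    imp_table = imp.importance_table(
        model.z, model.weights, atlas_retained, t2star_b_retained, pvs_b
    )
    manifest["outputs"]["importance"] = _write(
        imp_table, out_dir / "importance.tsv", cfg_hash
    )

    stage("iron")
    iron_b = iron_mod.iron_table(t2star_b, model.retained_idx)
    manifest["outputs"]["iron"] = _write(iron_b, out_dir / "iron.tsv", cfg_hash)

    stage("risk")
    imaging = subjects[subjects["has_imaging"] == 1]
    scheme = estimate_ipw(subjects, imaging, config.outcome)
    fit_cont = weighted_logistic(table_b, config.outcome, pvs_b, weights=scheme)
    manifest["outputs"]["risk_continuous"] = _write(
        fit_cont.table, out_dir / "risk_continuous.tsv", cfg_hash
    )
    # subsample C: B plus all homozygotes (no quantile for homozygotes)
    c_mask = subsample_c_mask(subjects)
    table_c = subjects.loc[c_mask].reset_index(drop=True)
    hom_c = (table_c["genotype_class"] == "homozygote").to_numpy(bool)
    pvs_map = dict(zip(scores["subject_id"], scores["pvs"]))
    pvs_c = np.array([pvs_map.get(s, np.nan) for s in table_c["subject_id"]])
    pvs_c[hom_c] = 0.0  # placeholder; homozygotes enter as their own category
    fit_quant = quantile_risk(
        table_c, pvs_c, hom_c, config.outcome, weights=scheme
    )
    manifest["outputs"]["risk_quantile"] = _write(
        fit_quant.table, out_dir / "risk_quantile.tsv", cfg_hash
    )
    manifest["risk"] = {"ipw_case_weight": scheme.case_weight}

    stage("replicate")
    if truth.variant_dosages is not None and np.any(truth.variant_effects):
        geno = pd.DataFrame(
            truth.variant_dosages[np.asarray(b_mask)],
            columns=[f"v{j}" for j in range(truth.variant_dosages.shape[1])],
        ).reset_index(drop=True)
        rng = np.random.default_rng(config.seed)
        n_b = len(table_b)
        disc = rng.permutation(n_b) < int(config.discovery_fraction * n_b)
        assoc_d = rep.mass_univariate_assoc(geno[disc], pvs_b[disc])
        assoc_r = rep.mass_univariate_assoc(geno[~disc], pvs_b[~disc])
        sel = assoc_d.loc[
            (assoc_d["tested"]) & (assoc_d["p"] < config.selection_p), "variant"
        ].tolist()
        if sel:
            conc = rep.sign_concordance(assoc_d, assoc_r, sel)
            manifest["replication"] = {
                "n_selected": conc.n_selected,
                "proportion_concordant": conc.proportion,
                "p_value": conc.p_value,
                "beta_correlation": conc.beta_correlation,
            }
        manifest["outputs"]["assoc_discovery"] = _write(
            assoc_d, out_dir / "assoc_discovery.tsv", cfg_hash
        )
        manifest["outputs"]["assoc_replication"] = _write(
            assoc_r, out_dir / "assoc_replication.tsv", cfg_hash
        )

    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
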