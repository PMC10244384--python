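"""End-to-end pipeline orchestration with a serialisable run configuration.

Stages run in dependency order: simulation (or loading of user tables),
4-mer distances, UPGMA clustering with hotspot search and its permutation
null, the contact-count half-life fit, logistic classifier training with
evaluation and cross-validation, and the repertoire %HA enrichment test. A
machine-readable manifest records the package version, seed, parameters and
every stage that ran.

A single global seed is expanded into independent per-stage streams keyed by
a fixed stage code, so toggling one stage never shifts the randomness of
another.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from . import io as tio
from .atchley import distance_matrix
from .classifier import (
    AvidityLogisticModel,
    FeatureDefinition,
    cross_validate,
    evaluate_classifier,
    overall_success,
)
from .clustering import cluster_enrichment_null, find_hotspot, upgma
from .contacts import ContactHalfLifeModel
from .core import HIGH_AVIDITY_THRESHOLD_S, INTERMEDIATE_AVIDITY_THRESHOLD_S
from .repertoire import ha_enrichment_test, label_repertoire
from .simulate import ContactSpec, PanelSpec, generate_contacts, generate_panel, generate_repertoires

#: fixed per-stage codes for seed expansion (stage toggling must not shift
#: downstream randomness)
_STAGE_CODES = {"simulate": 1, "cluster_null": 2, "crossval": 3, "enrich": 4,
                "repertoires": 5}


def stage_seed(global_seed: int, stage: str) -> int:
    """Independent 31-bit stream seed for one named stage."""
    ss = np.random.SeedSequence([int(global_seed), _STAGE_CODES[stage]])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


@dataclass
class RunConfig:
    """Everything a full run needs; round-trips losslessly through JSON."""

    outdir: str = "tcravidity_run"
    seed: int = 0
    # stage toggles
    simulate: bool = True
    distance: bool = True
    cluster: bool = True
    contacts: bool = True
    train: bool = True
    crossval: bool = True
    enrich: bool = True
    # input paths (used when simulate is off)
    panel_path: Optional[str] = None
    exposure_path: Optional[str] = None
    contacts_path: Optional[str] = None
    blood_path: Optional[str] = None
    tumor_path: Optional[str] = None
    # stage parameters
    exposure_threshold: float = 0.30
    high_threshold_s: float = HIGH_AVIDITY_THRESHOLD_S
    intermediate_threshold_s: float = INTERMEDIATE_AVIDITY_THRESHOLD_S
    permutation_replicates: int = 1000
    min_clade_size: int = 5
    cv_folds: int = 5
    cv_reps: int = 1
    # simulation parameters
    n_tcrs: int = 48
    high_fraction: float = 11 / 48
    coupled_exposure: bool = True
    motif: Optional[str] = None
    n_complexes: int = 10
    contact_noise_sd: float = 0.0
    tumor_high_bias: float = 3.0
    # demo-scale read depth: shallow enough that some clonotypes are found in
    # only one compartment, so the infiltrating / non-infiltrating partition
    # of the enrichment test is nondegenerate
    depth: int = 300

    def __post_init__(self) -> None:
        if self.permutation_replicates < 1:
            raise ValueError("permutation_replicates must be >= 1")
        if self.min_clade_size < 2:
            raise ValueError("min_clade_size must be >= 2")
        for name in ("exposure_threshold", "high_threshold_s", "intermediate_threshold_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_json(self, path: Optional[str] = None) -> str:
        text = json.dumps(dataclasses.asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text

    @classmethod
    def from_json(cls, source: str) -> "RunConfig":
        path = Path(source)
        text = path.read_text(encoding="utf-8") if path.exists() else source
        return cls(**json.loads(text))


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages and write a result bundle to disk.

    Returns the manifest dictionary (also written as ``manifest.json``).
    Stage dependencies are checked up front: distances need a panel, the
    cluster stage needs distances, training needs a panel with half-lives and
    exposures, and enrichment needs repertoires plus a trained classifier.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "tcravidity",
        "version": __version__,
        "seed": config.seed,
        "config": json.loads(config.to_json()),
        "stages": [],
        "outputs": [],
    }

    def emit(name: str) -> Path:
        manifest["outputs"].append(name)
        return outdir / name

    # --- dependency validation before any execution -----------------------
    problems = []
    if not config.simulate:
        if (config.distance or config.train) and config.panel_path is None:
            problems.append("distance/train stages need panel_path when simulate is off")
        if config.train and config.exposure_path is None:
            problems.append("train stage needs exposure_path when simulate is off")
        if config.contacts and config.contacts_path is None:
            problems.append("contacts stage needs contacts_path when simulate is off")
        if config.enrich and (config.blood_path is None or config.tumor_path is None):
            problems.append("enrich stage needs blood_path and tumor_path when simulate is off")
    if config.cluster and not config.distance:
        problems.append("cluster stage requires the distance stage")
    if config.enrich and not config.train:
        problems.append("enrich stage requires the train stage (predicted labels)")
    if problems:
        raise ValueError("invalid stage configuration: " + "; ".join(problems))

    # --- simulate / load --------------------------------------------------
    panel = exposures = contact_records = None
    blood = tumor = None
    if config.simulate:
        spec = PanelSpec(
            n_tcrs=config.n_tcrs,
            high_fraction=config.high_fraction,
            coupled_exposure=config.coupled_exposure,
            motif=config.motif,
            seed=stage_seed(config.seed, "simulate"),
        )
        panel, exposures = generate_panel(spec)
        contact_records = generate_contacts(
            ContactSpec(
                n_complexes=config.n_complexes,
                noise_sd=config.contact_noise_sd,
                seed=stage_seed(config.seed, "simulate"),
            )
        )
        blood_s, tumor_s = generate_repertoires(
            panel,
            tumor_high_bias=config.tumor_high_bias,
            depth=config.depth,
            seed=stage_seed(config.seed, "repertoires"),
        )
        blood, tumor = blood_s, tumor_s
        tio.write_clonotype_table(panel, emit("panel.tsv"))
        tio.write_exposure_table(exposures, emit("exposure.tsv"))
        tio.write_contact_table(contact_records, emit("contacts.tsv"))
        blood.table.to_csv(emit("repertoire_blood.tsv"), sep="\t", index=False)
        tumor.table.to_csv(emit("repertoire_tumor.tsv"), sep="\t", index=False)
        manifest["stages"].append("simulate")
    else:
        if config.panel_path:
            panel = tio.read_clonotype_table(config.panel_path)
        if config.exposure_path:
            exposure_map = tio.read_exposure_table(config.exposure_path)
            exposures = [exposure_map[c.tcr_id] for c in panel]
        if config.contacts_path:
            contact_records = tio.read_contact_table(config.contacts_path)
        if config.blood_path and config.tumor_path:
            from .simulate import RepertoireSample

            blood = RepertoireSample("blood", tio.read_repertoire_table(config.blood_path))
            tumor = RepertoireSample("tumor", tio.read_repertoire_table(config.tumor_path))

    # --- distances and clustering ----------------------------------------
    if config.distance:
        dm = distance_matrix(panel)
        tio.write_distance_matrix(dm, emit("distance_matrix.tsv"))
        tio.write_distance_long(dm, emit("distance_long.tsv"))
        manifest["stages"].append("distance")
        if config.cluster:
            tree = upgma(dm)
            emit("tree.nwk").write_text(tree.to_newick() + "\n", encoding="utf-8")
            halflives = {c.tcr_id: c.halflife_s for c in panel}
            hotspot = find_hotspot(
                tree,
                halflives,
                threshold_s=config.intermediate_threshold_s,
                min_size=config.min_clade_size,
            )
            p = cluster_enrichment_null(
                tree,
                halflives,
                hotspot.purity,
                threshold_s=config.intermediate_threshold_s,
                min_size=config.min_clade_size,
                b=config.permutation_replicates,
                seed=stage_seed(config.seed, "cluster_null"),
            )
            hotspot.p_value = p
            pd.DataFrame(
                [
                    {
                        "members": ",".join(hotspot.member_ids),
                        "purity": hotspot.purity,
                        "inside_high_fraction": hotspot.inside_high_fraction,
                        "outside_low_fraction": hotspot.outside_low_fraction,
                        "threshold_s": hotspot.threshold_s,
                        "min_size": hotspot.min_size,
                        "p_value": p,
                    }
                ]
            ).to_csv(emit("hotspot.tsv"), sep="\t", index=False)
            manifest["stages"].append("cluster")

    # --- contact model ----------------------------------------------------
    if config.contacts:
        fit = ContactHalfLifeModel.from_records(contact_records).fit()
        tio.write_keyvalues(fit.to_keyvalues(), emit("contact_model.tsv"))
        manifest["stages"].append("contacts")

    # --- classifier -------------------------------------------------------
    results = None
    if config.train:
        labeled = [
            (c, e)
            for c, e in zip(panel, exposures)
            if c.halflife_s is not None
        ]
        cdr3bs = [c.cdr3b for c, _ in labeled]
        labels = [int(c.halflife_s > config.high_threshold_s) for c, _ in labeled]
        profs = [e for _, e in labeled]
        fdef = FeatureDefinition(exposure_threshold=config.exposure_threshold)
        model = AvidityLogisticModel.from_panel(cdr3bs, labels, fdef, profs)
        results = model.fit()
        tio.write_logistic_model(results, emit("logistic_model.tsv"))
        metrics = evaluate_classifier(results, model.X, labels)
        pd.DataFrame([metrics]).to_csv(emit("classifier_metrics.tsv"), sep="\t", index=False)
        manifest["stages"].append("train")
        if config.crossval:
            rows = []
            seed = stage_seed(config.seed, "crossval")
            epitopes = [c.pmhc for c, _ in labeled]
            for scheme in ("leave20out_random", "leave20out_stratified", "leave_one_epitope_out"):
                folds = cross_validate(
                    model.X,
                    labels,
                    scheme,
                    epitopes=epitopes if scheme == "leave_one_epitope_out" else None,
                    n_folds=config.cv_folds,
                    reps=config.cv_reps,
                    seed=seed,
                )
                rows.append({"scheme": scheme, "success": overall_success(folds)})
            pd.DataFrame(rows).to_csv(emit("crossval.tsv"), sep="\t", index=False)
            manifest["stages"].append("crossval")

    # --- repertoire enrichment -------------------------------------------
    if config.enrich:
        calls = results.predict_label(results.model.X)
        reference = {
            c.cdr3b: ("high" if call else "low")
            for (c, _), call in zip(labeled, calls)
        }
        blood_l = label_repertoire(reference, blood)
        tumor_l = label_repertoire(reference, tumor)
        result = ha_enrichment_test(
            tumor_l,
            blood_l,
            b=config.permutation_replicates,
            seed=stage_seed(config.seed, "enrich"),
        )
        pd.DataFrame([dataclasses.asdict(result)]).to_csv(
            emit("ha_enrichment.tsv"), sep="\t", index=False
        )
        manifest["stages"].append("enrich")

    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2) + "\n", encoding="utf-8"
    )
    return manifest
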