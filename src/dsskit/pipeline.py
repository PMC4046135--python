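"""End-to-end DSRT analysis pipeline with a reproducibility manifest.

Wires the library stages (normalize -> fit -> score -> differential ->
subgroups -> cluster -> kiss) behind a flat YAML-serializable
:class:`RunConfig`.  Every stochastic stage takes its seed from the config;
re-running the same config reproduces byte-identical numeric outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .curves import (
    PlateControls,
    ScoreMatrix,
    curves_from_frame,
    _validate_drt_frame,
    normalize_viability,
    read_plate_controls,
    read_score_matrix,
    write_score_matrix,
)
from .clustering import (
    Partition,
    ResponseProfileClustering,
    index_difference_permutation_test,
    partition_indices,
)
from .kiss import addiction_network, export_network, kiss_profile, read_target_matrix
from .scoring import ScoreSettings, differential_scores, fits_to_frame, score_curves
from .stats import subgroup_table

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

logger = logging.getLogger(__name__)

STAGES = ("normalize", "fit", "score", "differential", "subgroups", "cluster", "kiss")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and the cause."""


@dataclass
class RunConfig:
    """Flat pipeline configuration (YAML round-trippable).

    ``control_sample_ids`` enables differential scoring; ``moa_path`` enables
    clustering evaluation; ``targets_path`` enables KISS.  ``raw_input``
    marks the response column as raw readouts to be normalized with the
    plate controls in ``controls_path``.
    """

    schema_version: int = 1
    drt_path: str = ""
    out_dir: str = "dsskit_out"
    controls_path: str | None = None
    raw_input: bool = False
    control_sample_ids: list[str] = field(default_factory=list)
    differential: bool = False
    moa_path: str | None = None
    targets_path: str | None = None
    expressed_path: str | None = None
    metric: str = "DSS2"
    compare_metric: str = "AA"
    a_min: float = 10.0
    x_lo: float | None = None
    x_hi: float | None = None
    alpha: float = 0.05
    n_perm: int = 10000
    seed: int = 0
    kiss_threshold: float = 5.0
    corr_threshold: float = 0.5
    verbosity: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _normalize_stage(df: pd.DataFrame, cfg: RunConfig) -> pd.DataFrame:
    if not cfg.raw_input:
        return df
    if not cfg.controls_path:
        raise ValueError("raw_input is set but controls_path is missing")
    controls = read_plate_controls(cfg.controls_path)
    out = df.copy()
    if "plate_id" in df.columns:
        for plate, grp in df.groupby("plate_id"):
            ctrl = controls[str(plate)]
            out.loc[grp.index, "response"] = normalize_viability(
                grp["response"].to_numpy(), ctrl)
    else:
        if len(controls) != 1:
            raise ValueError("multiple plates in controls file but no plate_id column")
        (ctrl,) = controls.values()
        out["response"] = normalize_viability(df["response"].to_numpy(), ctrl)
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Run every enabled stage and return the manifest (also written to disk).

    Partial outputs are kept on failure; the manifest marks the failing
    stage FAILED and the raised :class:`PipelineError` names it.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "dsskit_version": __version__,
        "config_hash": config.digest(),
        "seed": config.seed,
        "stages": {},
        "outputs": [],
    }

    def record(stage: str, status: str, *files) -> None:
        manifest["stages"][stage] = status
        manifest["outputs"].extend(str(f) for f in files)
        with open(out / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2)

    state: dict = {}

    def run_stage(stage: str, func) -> None:
        try:
            files = func() or ()
            record(stage, "completed", *files)
        except Exception as exc:
            record(stage, f"FAILED: {exc}")
            raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    def normalize():
        df = pd.read_csv(config.drt_path, comment="#")
        state["table"] = _normalize_stage(_validate_drt_frame(df), config)
        path = out / "normalized.csv"
        state["table"].to_csv(path, index=False)
        return (path,)

    def fit():
        settings = ScoreSettings(a_min=config.a_min, x_lo=config.x_lo,
                                 x_hi=config.x_hi, metric=config.metric.upper())
        state["settings"] = settings
        curves = curves_from_frame(state["table"])
        state["curves"] = curves
        matrix, fits = score_curves(curves, settings)
        state["matrix"], state["fits"] = matrix, fits
        path = out / "fits.csv"
        fits_to_frame(fits).to_csv(path, index=False)
        return (path,)

    def score():
        path = out / f"scores_{config.metric.lower()}.csv"
        write_score_matrix(state["matrix"], path)
        files = [path]
        if config.compare_metric:
            cmp_settings = ScoreSettings(a_min=config.a_min, x_lo=config.x_lo,
                                         x_hi=config.x_hi,
                                         metric=config.compare_metric.upper())
            cmp_matrix, _ = score_curves(state["curves"], cmp_settings)
            state["compare_matrix"] = cmp_matrix
            cmp_path = out / f"scores_{config.compare_metric.lower()}.csv"
            write_score_matrix(cmp_matrix, cmp_path)
            files.append(cmp_path)
        return files

    def differential():
        if not config.control_sample_ids:
            if config.differential:
                raise ValueError(
                    "differential scoring (dDSS) requested but control_sample_ids is missing")
            state["ddss"] = state["matrix"]
            return ()
        ddss = differential_scores(state["matrix"], config.control_sample_ids)
        state["ddss"] = ddss
        path = out / "ddss.csv"
        write_score_matrix(ddss, path)
        return (path,)

    def subgroups():
        table = subgroup_table(state["ddss"].values, alpha=config.alpha)
        state["subgroups"] = table
        path = out / "subgroups.csv"
        table.to_csv(path, index=False)
        return (path,)

    def cluster():
        if not config.moa_path:
            return ()
        moa = pd.read_csv(config.moa_path, comment="#")
        reference = Partition.from_mapping(
            dict(zip(moa["drug_id"].astype(str), moa["moa_class"].astype(str))))
        model = ResponseProfileClustering().fit(state["ddss"].values.T)
        part = model.partition_
        part_df = pd.DataFrame({"drug_id": part.item_ids, "cluster": part.labels})
        part_path = out / "partition.csv"
        part_df.to_csv(part_path, index=False)
        common = [d for d in part.item_ids if d in set(reference.item_ids)]
        sub_ref = Partition(tuple(common), reference.aligned_labels(common))
        sub_a = Partition(tuple(common), part.aligned_labels(common))
        idx = partition_indices(sub_a, sub_ref)
        files = [part_path]
        idx_path = out / "cluster_indices.csv"
        pd.DataFrame([idx]).to_csv(idx_path, index=False)
        files.append(idx_path)
        nwk_path = out / "dendrogram.nwk"
        nwk_path.write_text(model.dendrogram_.to_newick() + "\n", encoding="utf-8")
        files.append(nwk_path)
        if "compare_matrix" in state:
            cmp_model = ResponseProfileClustering().fit(state["compare_matrix"].values.T)
            sub_b = Partition(tuple(common), cmp_model.partition_.aligned_labels(common))
            perm = index_difference_permutation_test(
                sub_a, sub_b, sub_ref, n_perm=config.n_perm, seed=config.seed)
            perm_path = out / "cluster_permutation.csv"
            perm.to_csv(perm_path, index=False)
            files.append(perm_path)
        return files

    def kiss():
        if not config.targets_path:
            return ()
        targets = read_target_matrix(config.targets_path)
        expressed = None
        if config.expressed_path:
            expressed = [l.strip() for l in open(config.expressed_path, encoding="utf-8")
                         if l.strip()]
        sub = state["subgroups"]
        skew_p = pd.Series(sub["p_skew"].to_numpy(), index=sub["drug_id"].astype(str))
        ddss = state["ddss"].values
        files = []
        kiss_rows = {}
        for sample in ddss.index:
            prof = kiss_profile(ddss.loc[sample], targets, skew_p,
                                alpha=config.alpha, sample_id=str(sample))
            kiss_rows[sample] = prof.as_series()
            net = addiction_network(prof, targets, config.kiss_threshold,
                                    config.corr_threshold, expressed)
            sif = out / f"kiss_{sample}.sif"
            export_network(net, sif, "SIF")
            files.append(sif)
        kiss_path = out / "kiss.csv"
        pd.DataFrame(kiss_rows).T.rename_axis("sample_id").to_csv(kiss_path)
        files.append(kiss_path)
        return files

    for stage, func in zip(STAGES, (normalize, fit, score, differential,
                                    subgroups, cluster, kiss)):
        run_stage(stage, func)
        logger.info("stage %s: %s", stage, manifest["stages"][stage])
    return manifest
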