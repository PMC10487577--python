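"""End-to-end orchestration: spectra -> CCI -> PCoA -> dendrogram -> NJ tree
-> concordance, with deterministic, provenance-stamped artifacts.

All randomness flows from the single run seed via named substreams, so a
config + seed pair reproduces every artifact byte for byte (no timestamps
are written into artifacts).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .clustering import Dendrogram, linkage_single
from .concordance import cut_rooted_tree, grouping_similarity, sankey_table
from .io import write_peak_table
from .matrices import DistanceMatrix
from .ordination import pcoa
from .phylo import bootstrap_support, neighbor_joining, pairwise_distance
from .preprocess import DenoiseParams, SpectrumPreprocessor
from .similarity import (
    CCIParams,
    bray_curtis_matrix,
    cci_matrix,
    cci_summary,
    strain_level_matrix,
)
from .spectra import GridSpec, SpectrumSet
from .synthetic import SimConfig, simulate_dataset

__all__ = ["RunConfig", "run_end_to_end"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    output_dir: str = "maldiclust_out"
    seed: int = 0
    synthetic: dict = field(default_factory=dict)  # SimConfig overrides; None -> file input
    manifest: str | None = None  # file-input mode
    spectra_dir: str | None = None
    fasta: str | None = None
    grid: dict = field(default_factory=dict)  # start/stop/step
    denoise: dict = field(default_factory=dict)  # window/keep_fraction/step/combine_rule
    preprocess_order: str = "log_then_denoise"
    cci: dict = field(default_factory=dict)  # n_intervals/clamp_negative
    cut_k: int = 4
    distance_model: str = "jc69"
    bootstrap: int = 100
    concordance_method: str = "cogroup"
    write_inputs: bool = True

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def grid_spec(self) -> GridSpec:
        return GridSpec(
            start=self.grid.get("start", 2000.0),
            stop=self.grid.get("stop", 20000.0),
            step=self.grid.get("step", 1.0),
        )

    def denoise_params(self) -> DenoiseParams:
        return DenoiseParams(
            window_width=self.denoise.get("window", 100.0),
            keep_fraction=self.denoise.get("keep_fraction", 0.2),
            step=self.denoise.get("step", 1.0),
            combine_rule=self.denoise.get("combine_rule", "union"),
        )

    def cci_params(self) -> CCIParams:
        return CCIParams(
            n_intervals=self.cci.get("n_intervals", 10),
            clamp_negative=self.cci.get("clamp_negative", True),
        )

    def sim_config(self) -> SimConfig:
        return SimConfig(seed=self.seed, **self.synthetic)


def _config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(cfg.to_dict(), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_end_to_end(cfg: RunConfig) -> dict[str, Path]:
    """Run every stage and write the artifact bundle; returns name -> path."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    def emit(name: str, fname: str) -> Path:
        artifacts[name] = out / fname
        return artifacts[name]

    # --- stage: inputs -------------------------------------------------
    stage = "input"
    try:
        if cfg.synthetic is not None and cfg.manifest is None:
            dataset = simulate_dataset(cfg.sim_config())
            raws, manifest = dataset.spectra, dataset.manifest
            alignment = dataset.alignment
            if cfg.write_inputs:
                spectra_dir = out / "spectra"
                spectra_dir.mkdir(exist_ok=True)
                rows = {}
                for raw in raws:
                    fname = f"{raw.strain_id}_{raw.replicate_id}.tsv"
                    write_peak_table(raw, spectra_dir / fname)
                    rows.setdefault(raw.strain_id, []).append(fname)
                mtab = manifest.table.copy()
                mtab["file"] = [";".join(rows[s]) for s in mtab["strain_id"]]
                mtab.to_csv(emit("manifest", "manifest.csv"), index=False)
                alignment.write_fasta(emit("alignment", "sequences_16s.fasta"))
                emit("true_tree", "true_species_tree.nwk").write_text(
                    dataset.true_tree_newick + "\n"
                )
                with open(emit("truth", "truth.json"), "w") as fh:
                    json.dump(dataset.truth, fh, indent=2, sort_keys=True)
                    fh.write("\n")
        else:
            from .io import load_spectrum_set
            from .phylo import Alignment

            sset = load_spectrum_set(
                cfg.manifest,
                cfg.spectra_dir,
                grid=cfg.grid_spec(),
                denoise_params=cfg.denoise_params(),
                order=cfg.preprocess_order,
            )
            raws, manifest = None, sset.manifest
            alignment = Alignment.read_fasta(cfg.fasta) if cfg.fasta else None

        # --- stage: preprocessing --------------------------------------
        stage = "preprocess"
        if raws is not None:
            grid = cfg.grid_spec()
            dp = cfg.denoise_params()
            pre = SpectrumPreprocessor(
                start=grid.start,
                stop=grid.stop,
                grid_step=grid.step,
                window_width=dp.window_width,
                keep_fraction=dp.keep_fraction,
                denoise_step=dp.step,
                combine_rule=dp.combine_rule,
                order=cfg.preprocess_order,
            )
            sset = SpectrumSet(pre.transform_spectra(raws), manifest, grid)

        # --- stage: similarity -----------------------------------------
        stage = "similarity"
        spectrum_cci = cci_matrix(sset, cfg.cci_params())
        strain_cci = strain_level_matrix(spectrum_cci, sset.strain_ids)
        strain_cci.to_csv(emit("cci_matrix", "cci_matrix.csv"))
        cci_summary(strain_cci).to_csv(emit("cci_summary", "cci_summary.csv"), index=False)
        bc = bray_curtis_matrix(sset)
        bc.to_csv(emit("bray_curtis", "bray_curtis.csv"))

        # --- stage: ordination -----------------------------------------
        stage = "ordination"
        result = pcoa(bc)
        result.to_csv(emit("pcoa", "pcoa_coordinates.csv"))

        # --- stage: clustering -----------------------------------------
        stage = "clustering"
        dist = DistanceMatrix(strain_cci.labels, 1.0 - strain_cci.values)
        dendrogram = linkage_single(dist)
        emit("dendrogram", "dendrogram.nwk").write_text(dendrogram.to_newick() + "\n")
        ms_groups = dendrogram.cut(cfg.cut_k)
        ms_groups.to_csv(emit("ms_groups", "ms_groups.csv"))

        # --- stage: phylogeny ------------------------------------------
        stage = "phylogeny"
        nj_tree = None
        if alignment is not None:
            if cfg.bootstrap > 0:
                nj_tree = bootstrap_support(
                    alignment, model=cfg.distance_model, n_reps=cfg.bootstrap, seed=cfg.seed
                )
            else:
                nj_tree = neighbor_joining(pairwise_distance(alignment, cfg.distance_model))
            emit("nj_tree", "nj_tree.nwk").write_text(nj_tree.to_newick() + "\n")

        # --- stage: concordance ----------------------------------------
        stage = "concordance"
        if nj_tree is not None:
            report = grouping_similarity(
                dendrogram,
                nj_tree,
                manifest,
                method=cfg.concordance_method,
                k=cfg.cut_k if cfg.concordance_method == "cut" else None,
            )
            seq_groups = cut_rooted_tree(nj_tree, cfg.cut_k)
            report.sankey_edges = sankey_table(ms_groups, seq_groups)
            report.to_csv(emit("concordance_report", "concordance_report.csv"))
            report.to_json(emit("concordance_summary", "concordance_summary.json"))
            report.sankey_edges.to_csv(emit("sankey", "sankey_edges.csv"), index=False)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    # --- run log (no timestamps: artifacts must be reproducible) -------
    log = {
        "version": __version__,
        "seed": cfg.seed,
        "config": cfg.to_dict(),
        "config_hash": _config_hash(cfg),
        "n_spectra": len(sset),
        "n_strains": len(manifest),
        "artifacts": {k: str(v.name) for k, v in artifacts.items()},
    }
    with open(emit("run_log", "run_log.json"), "w") as fh:
        json.dump(log, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return artifacts
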