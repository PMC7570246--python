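"""End-to-end analysis orchestration.

One config drives the whole chain — score -> diversity -> distances ->
AMOVA/PCoA/Mantel -> NJ — on read or simulated matrices, writing CSV/JSON/
Newick outputs plus a manifest.  Every stage calls the same public module
functions a user would call directly; there are no pipeline-only code paths.

Randomness: the single global seed is fanned out to per-stage seeds through a
fixed CRC32 derivation of the stage name, so adding a stage never perturbs
the random streams of existing ones, and two runs with the same seed are
byte-identical.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .amova import amova, amova_frame
from .band_data import (
    BandMatrix,
    Grouping,
    merge_marker_systems,
    read_band_matrix,
    write_band_matrix,
    write_sample_metadata,
)
from .diversity import diversity_summary, summary_frame
from .distances import mantel, pairwise_distance, pcoa
from .methylation import count_band_types, methylation_rates, rate_contrasts
from .simulate import SimConfig, simulate_study
from .trees import neighbor_joining

__all__ = ["RunConfig", "run_pipeline", "stage_seed"]

log = logging.getLogger("epidiv")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Inputs and knobs for one pipeline run.

    Exactly one of ``inputs`` (mapping marker system -> matrix path, plus a
    shared ``meta`` path) or ``simulate`` (a :class:`SimConfig`) must be
    given.
    """

    out_dir: str
    seed: int
    inputs: dict[str, str] | None = None  # {"MSAP": path, "TMD": path, "meta": path}
    simulate: SimConfig | None = None
    grouping_level: str = "treatment_class"
    n_permutations: int = 999
    metric: str = "squared_euclidean"
    reference_group: str | None = None  # contrast reference; default first group

    def __post_init__(self) -> None:
        if (self.inputs is None) == (self.simulate is None):
            raise ValueError("exactly one of 'inputs' and 'simulate' must be set")
        if self.n_permutations > 0 and self.seed is None:
            raise ValueError("a seed is mandatory when permutation tests run")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        sim = raw.pop("simulate", None)
        if sim is not None:
            sim = SimConfig(**sim) if isinstance(sim, dict) else SimConfig()
        return cls(simulate=sim, **raw)


def stage_seed(global_seed: int, stage: str) -> int:
    """Per-stage seed: fixed CRC32 fan-out of the stage name."""
    return (global_seed * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)


def _load_matrices(config: RunConfig) -> tuple[dict[str, BandMatrix], int | None]:
    if config.simulate is not None:
        seed = stage_seed(config.seed, "simulate")
        sim = SimConfig(**{**config.simulate.__dict__, "seed": seed})
        return {k: bm for k, (bm, _) in simulate_study(sim).items()}, seed
    paths = dict(config.inputs or {})
    meta = paths.pop("meta")
    return {sys_: read_band_matrix(p, meta, sys_) for sys_, p in paths.items()}, None


def _write_distance(d, path: Path) -> None:
    pd.DataFrame(d.data, index=d.sample_ids, columns=d.sample_ids).to_csv(path)


def run_pipeline(config: RunConfig) -> dict:
    """Run the full chain; returns a manifest dict (also written to disk).

    On a stage failure, outputs produced so far stay in place, a ``FAILED``
    marker file names the stage, and :class:`PipelineError` is raised.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "epidiv_version": __version__,
        "seed": config.seed,
        "grouping_level": config.grouping_level,
        "metric": config.metric,
        "n_permutations": config.n_permutations,
        "stage_seeds": {},
        "outputs": [],
        "decisions": {
            "distance_convention": "squared_euclidean entries are squared distances; "
            "AMOVA and PCoA consume them as such",
            "rate_display": "percentages reported at 2 decimals, round-half-up",
            "negative_variance_components": "truncated at zero; raw value kept",
        },
    }
    stage = "load"
    try:
        matrices, sim_seed = _load_matrices(config)
        if sim_seed is not None:
            manifest["stage_seeds"]["simulate"] = sim_seed
        systems = sorted(matrices)
        if config.simulate is not None:
            for sys_ in systems:
                p = out / f"{sys_.lower()}_matrix.csv"
                write_band_matrix(matrices[sys_], p)
                manifest["outputs"].append(p.name)
            meta_p = out / "metadata.csv"
            write_sample_metadata(matrices[systems[0]].samples, meta_p)
            manifest["outputs"].append(meta_p.name)
        if len(systems) >= 2:
            merged = matrices[systems[0]]
            for sys_ in systems[1:]:
                merged = merge_marker_systems(merged, matrices[sys_])
            matrices = {**matrices, "MERGED": merged}
        else:
            log.info("single marker system: merged outputs and Mantel skipped")

        distances = {}
        for sys_, bm in sorted(matrices.items()):
            tag = sys_.lower()
            grouping = Grouping.from_samples(bm.samples, config.grouping_level)
            group_grouping = Grouping.from_samples(bm.samples, "treatment_group")

            stage = f"score:{tag}"
            counts = count_band_types(bm, group_grouping)
            profiles = [(c.group, methylation_rates(c, ndigits=2)) for c in counts]
            rates_rows = [
                {"group": g, **{f"{r}_pct": p.rate(r) for r in ("total", "full", "hemi", "non")}}
                for g, p in profiles
            ]
            rates_path = out / f"{tag}_rates.csv"
            pd.DataFrame(rates_rows).to_csv(rates_path, index=False)
            ref = config.reference_group or profiles[0][0]
            class_map = {s.treatment_group: s.treatment_class for s in bm.samples}
            contrasts = rate_contrasts(profiles, reference=ref, class_map=class_map)
            contrasts_path = out / f"{tag}_contrasts.csv"
            contrasts.to_csv(contrasts_path, index=False)

            stage = f"diversity:{tag}"
            div = summary_frame(diversity_summary(bm, grouping))
            div_path = out / f"{tag}_diversity.csv"
            div.to_csv(div_path, index=False)

            stage = f"distance:{tag}"
            d = pairwise_distance(bm, config.metric)
            distances[sys_] = d
            dist_path = out / f"{tag}_distance.csv"
            _write_distance(d, dist_path)

            stage = f"amova:{tag}"
            seed = stage_seed(config.seed, f"amova:{sys_}")
            manifest["stage_seeds"][f"amova:{tag}"] = seed
            am = amova(d, grouping, config.n_permutations, seed)
            am_path = out / f"{tag}_amova.csv"
            amova_frame(am).to_csv(am_path, index=False)

            stage = f"pcoa:{tag}"
            pc = pcoa(d, n_axes=2)
            coords = pd.DataFrame(
                pc.coordinates,
                index=pc.sample_ids,
                columns=[f"axis{i + 1}" for i in range(pc.coordinates.shape[1])],
            )
            coords.insert(0, "group", [class_map[s.treatment_group]
                                       for s in bm.samples])
            pcoa_path = out / f"{tag}_pcoa.csv"
            with open(pcoa_path, "w") as fh:
                fh.write("# pct_explained: "
                         + ",".join(f"{v:.4f}" for v in pc.pct_explained) + "\n")
                coords.to_csv(fh, index_label="sample_id")

            stage = f"nj:{tag}"
            tree = neighbor_joining(d)
            nj_path = out / f"{tag}_nj.nwk"
            tree.write(str(nj_path))
            manifest["outputs"] += [rates_path.name, contrasts_path.name,
                                    div_path.name, dist_path.name, am_path.name,
                                    pcoa_path.name, nj_path.name]

        if len(systems) >= 2:
            stage = "mantel"
            seed = stage_seed(config.seed, "mantel")
            manifest["stage_seeds"]["mantel"] = seed
            mr = mantel(distances[systems[0]], distances[systems[1]],
                        config.n_permutations, seed)
            mantel_path = out / "mantel.json"
            mantel_path.write_text(json.dumps({
                "systems": systems[:2], "r": mr.r, "r_squared": mr.r_squared,
                "p_value": mr.p_value, "n_permutations": mr.n_permutations,
                "seed": mr.seed,
            }, indent=2))
            manifest["outputs"].append(mantel_path.name)
        stage = "manifest"
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        manifest["outputs"].append("manifest.json")
        return manifest
    except Exception as exc:  # pragma: no cover - exercised via error tests
        (out / "FAILED").write_text(f"stage: {stage}\ncause: {exc}\n")
        log.error("pipeline failed at stage %s: %s", stage, exc)
        raise PipelineError(stage, exc) from exc
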