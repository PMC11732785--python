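"""End-to-end orchestration: ingest -> filter -> orbits -> distances -> summaries.

Every run writes the full chain of intermediate artifacts (filter decisions,
orbit counts, distance matrix, cohort summaries, MDS coordinates, size
diagnostics) plus a JSON manifest of every decision flag, so each reported
number is recomputable from the emitted files alone.  Runs are deterministic:
the same inputs and config give byte-identical CSVs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .cohorts import (
    decade_summary,
    ecosystem_table,
    mds_embed,
    partition_from_metadata,
    publication_effect,
    publication_table,
    size_confound,
    threshold_shares,
)
from .graphlets import DistanceMatrix, count_orbits, pairwise_distances
from .net_io import (
    FoodWeb,
    WebMetadata,
    read_edgelist,
    read_metadata,
    write_matrix_csv,
)
from .preprocess import apply_inclusion_filters

logger = logging.getLogger("webprint")

_FLOAT_FMT = "%.10g"


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Defaults reproduce the main-text configuration: mean statistic, square
    root applied in the distance, cutoffs {1.5, 2.5}.
    """

    input_dir: str | Path | None = None
    metadata_path: str | Path | None = None
    out_dir: str | Path = "webprint_out"
    statistic: str = "mean"
    squared: bool = False  # report squared distances instead of Euclidean
    cutoffs: tuple[float, ...] = (1.5, 2.5)
    partitions: tuple[str, ...] = ("ecosystem", "publication", "ecopath", "aquatic_subtype")
    role_stage: str = "raw"
    drop_publication: str | None = None
    mds_dims: int = 2
    seed: int = 0


@dataclass
class RunResult:
    distance: DistanceMatrix
    decisions: pd.DataFrame
    summaries: dict[str, pd.DataFrame]
    manifest: dict
    out_dir: Path


def load_webs(input_dir: str | Path) -> list[FoodWeb]:
    """Read every edge-list file (*.csv, *.tsv, *.edges) in a directory."""
    input_dir = Path(input_dir)
    paths = sorted(
        p for p in input_dir.iterdir()
        if p.suffix in (".csv", ".tsv", ".edges") and p.stem != "metadata"
    )
    if not paths:
        raise FileNotFoundError(f"no edge-list files in {input_dir}")
    return [read_edgelist(p) for p in paths]


def run_all(
    config: RunConfig,
    webs: list[FoodWeb] | None = None,
    meta: list[WebMetadata] | None = None,
) -> RunResult:
    """Run the whole analysis; ``webs``/``meta`` may be passed in-memory
    instead of being read from ``config.input_dir``/``config.metadata_path``."""
    if webs is None:
        if config.input_dir is None:
            raise ValueError("either webs or config.input_dir is required")
        webs = load_webs(config.input_dir)
    if meta is None:
        if config.metadata_path is None:
            raise ValueError("either meta or config.metadata_path is required")
        meta = read_metadata(config.metadata_path)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    # 1. inclusion filters
    processed: list[FoodWeb] = []
    decisions = []
    for web in sorted(webs, key=lambda w: w.web_id):
        p, dec = apply_inclusion_filters(web, role_stage=config.role_stage)
        decisions.append({
            "web_id": dec.web_id, "included": dec.included,
            "reasons": ";".join(dec.reasons),
            "n_nodes_raw": dec.n_nodes_raw, "n_nodes_final": dec.n_nodes_final,
            "n_consumers": dec.n_consumers, "n_resources": dec.n_resources,
            "giant_component_fraction": dec.giant_component_fraction,
            "bipartite_warning": dec.bipartite_warning,
        })
        if p is not None:
            processed.append(p)
    decisions_df = pd.DataFrame(decisions)
    decisions_df.to_csv(out_dir / "filter_decisions.csv", index=False,
                        float_format=_FLOAT_FMT)
    if len(processed) < 2:
        raise RuntimeError(
            f"fewer than 2 webs survived the inclusion filters "
            f"(see {out_dir / 'filter_decisions.csv'})"
        )
    kept_ids = [w.web_id for w in processed]
    meta_by_id = {m.web_id: m for m in meta}
    kept_meta = [meta_by_id[w] for w in kept_ids if w in meta_by_id]

    # 2. orbit counts (single long table) and distance matrix
    orbit_frames = []
    for web in processed:
        df = count_orbits(web).to_dataframe().reset_index(names="node")
        df.insert(0, "web_id", web.web_id)
        orbit_frames.append(df)
    pd.concat(orbit_frames).to_csv(out_dir / "orbit_counts.csv", index=False)
    D = pairwise_distances(processed, squared=config.squared)
    write_matrix_csv(D.web_ids, D.values, out_dir / "distance_matrix.csv")

    # 3. cohort summaries
    summaries: dict[str, pd.DataFrame] = {}
    stat = config.statistic
    if "ecosystem" in config.partitions:
        summaries["ecosystem"] = ecosystem_table(D, kept_meta, stat)
        if config.drop_publication:
            summaries["ecosystem_dropped"] = ecosystem_table(
                D, kept_meta, stat, drop_publication=config.drop_publication
            )
    if "publication" in config.partitions:
        summaries["publication"] = publication_table(D, kept_meta, stat)
    if "ecopath" in config.partitions:
        aquatic = [m for m in kept_meta if m.ecosystem == "aquatic"]
        rows = []
        for flag in (True, False):
            ids = [m.web_id for m in aquatic if m.ecopath == flag]
            if len(ids) >= 2:
                from .cohorts import within_group_dispersion
                s = within_group_dispersion(D, ids, stat, label="ecopath" if flag else "non_ecopath")
                rows.append({"statistic": stat, "group": s.group, "value": s.value,
                             "n_webs": s.n_webs, "n_pairs": s.n_pairs})
        summaries["ecopath"] = pd.DataFrame(rows)
    if "aquatic_subtype" in config.partitions:
        aquatic = [m for m in kept_meta if m.ecosystem == "aquatic" and m.aquatic_subtype]
        rows = []
        from .cohorts import within_group_dispersion
        by_sub: dict[str, list[str]] = {}
        for m in aquatic:
            by_sub.setdefault(m.aquatic_subtype, []).append(m.web_id)
        for sub, ids in sorted(by_sub.items()):
            if len(ids) >= 2:
                s = within_group_dispersion(D, ids, stat, label=sub)
                rows.append({"statistic": stat, "group": sub, "value": s.value,
                             "n_webs": s.n_webs, "n_pairs": s.n_pairs})
            else:
                rows.append({"statistic": stat, "group": sub, "value": float("nan"),
                             "n_webs": len(ids), "n_pairs": 0})
        summaries["aquatic_subtype"] = pd.DataFrame(rows)

    summaries["decade"] = decade_summary(D, kept_meta, stat)
    summaries["threshold_shares"] = threshold_shares(D, kept_meta, list(config.cutoffs))

    pub_part = partition_from_metadata(kept_meta, "publication", kept_ids)
    try:
        effect = publication_effect(D, pub_part, stat)
    except ValueError:
        effect = None

    coords, stress = mds_embed(D, dims=config.mds_dims)
    coords.to_csv(out_dir / "mds_coords.csv", float_format=_FLOAT_FMT)

    sizes = {w.web_id: w.n_nodes for w in processed}
    try:
        summaries["size_confound"] = size_confound(D, sizes, pub_part, stat)
    except ValueError as exc:
        logger.info("size diagnostics skipped: %s", exc)

    for name, df in summaries.items():
        df.to_csv(out_dir / f"summary_{name}.csv", index=False, float_format=_FLOAT_FMT)

    manifest = {
        "webprint_version": __version__,
        "config": {k: (str(v) if isinstance(v, Path) else v)
                   for k, v in asdict(config).items()},
        "n_webs_input": len(webs),
        "n_webs_included": len(processed),
        "included_web_ids": kept_ids,
        "mds_stress": stress,
        "publication_effect": effect,
        "decision_flags": {
            "distance": "squared" if config.squared else "euclidean",
            "spearman_ties": "average_ranks",
            "zero_variance_rule": "all-ones pseudo-row, residual constants -> 0",
            "role_stage": config.role_stage,
            "giant_component_tie_break": "smallest lexicographic minimum label",
        },
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return RunResult(distance=D, decisions=decisions_df, summaries=summaries,
                     manifest=manifest, out_dir=out_dir)
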