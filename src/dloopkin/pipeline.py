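"""End-to-end orchestration: alignment -> QC -> tree -> haplogroups ->
connections -> PhiST -> ordination, with every intermediate written to a run
directory and a machine-readable summary.

All randomness flows from a single top-level seed expanded per stage.  A
supplied external tree (e.g. a maximum-likelihood tree built elsewhere)
always takes precedence over the internal neighbour-joining surrogate.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from dloopkin import io_formats, alignment_qc, tree_model, kinship_core
from dloopkin import popgen_fst, ordination

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths and parameters of one pipeline run.

    ``tree`` is either a Newick file path or the literal string
    ``"build-nj"`` to build the internal neighbour-joining surrogate from
    K2P distances.
    """

    alignment: str
    breed_table: str
    out_dir: str
    tree: str = "build-nj"
    haplogroup_references: str | None = None
    grouping: str | None = None
    outgroup: list[str] = field(default_factory=list)
    dedup: bool = True
    apply_conserved_mask: bool = False
    trim_reference_ids: list[str] = field(default_factory=list)
    max_missing_frac: float = 0.05
    min_individuals: int = 3
    retention_fraction: float = 0.75
    kinship_types: list[int] = field(default_factory=lambda: [1, 2])
    min_shared_sites: int = 50
    nmds_restarts: int = 20
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def validate(self) -> None:
        for p in [self.alignment, self.breed_table]:
            if not Path(p).exists():
                raise FileNotFoundError(p)
        if self.tree != "build-nj" and not Path(self.tree).exists():
            raise FileNotFoundError(self.tree)
        for p in [self.haplogroup_references, self.grouping]:
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)
        if not 0 <= self.max_missing_frac <= 1:
            raise ValueError("max_missing_frac must be in [0, 1]")
        if not 0 < self.retention_fraction <= 1:
            raise ValueError("retention_fraction must be in (0, 1]")
        if any(t not in (1, 2) for t in self.kinship_types):
            raise ValueError("kinship_types must be drawn from {1, 2}")


def summarize_haplogroups(
    assignment: tree_model.HaplogroupAssignment, breed_table: pd.DataFrame
) -> pd.DataFrame:
    """Region x haplogroup count table (rows sum to region sample sizes)."""
    meta = breed_table.set_index("id")
    rows = []
    for tip, hap in assignment.haplogroup.items():
        if tip in meta.index:
            rows.append((meta.at[tip, "region"], hap))
    df = pd.DataFrame(rows, columns=["region", "haplogroup"])
    table = (
        df.groupby(["region", "haplogroup"]).size().unstack(fill_value=0)
    )
    for h in tree_model.HAPLOGROUPS:
        if h not in table.columns and h in set(assignment.haplogroup.values()):
            table[h] = 0
    return table.sort_index(axis=1)


def _read_grouping(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str, header=None, comment="#")
    if df.iloc[0, 0].lower() in ("breed", "id"):
        df = df.iloc[1:]
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute every stage and write artifacts to the run directory.

    Deterministic given the config seed: reruns produce byte-identical
    numeric outputs.  Stage failures propagate with the stage named.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w", encoding="utf-8")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root_logger = logging.getLogger("dloopkin")
    root_logger.addHandler(handler)
    root_logger.setLevel(logging.INFO)
    summary: dict = {"seed": config.seed, "stages": []}
    seed_seq = np.random.SeedSequence(config.seed)
    stage_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in seed_seq.spawn(4)]

    def stage(name):
        summary["stages"].append(name)
        logger.info("stage: %s", name)

    try:
        stage("io")
        records = io_formats.read_fasta(config.alignment)
        breed_table = io_formats.read_breed_table(config.breed_table)
        records = io_formats.attach_metadata(records, breed_table)
        if config.dedup:
            records, report = io_formats.dedup_identical_within_breed(records)
            summary["dedup_removed"] = len(report)
        aln = alignment_qc.MsAlignment(records=records)

        stage("qc")
        if config.trim_reference_ids:
            aln = alignment_qc.trim_protruding_ends(aln, config.trim_reference_ids)
        if config.apply_conserved_mask:
            mask = alignment_qc.conserved_block_mask(aln)
            aln = aln.take_columns(mask)
        summary["qc_columns"] = aln.length
        summary["qc_sequences"] = aln.n_sequences
        io_formats.write_fasta(aln.records, out / "qc_alignment.fasta")
        kept_ids = set(aln.ids())
        io_formats.write_breed_table(
            breed_table[breed_table["id"].isin(kept_ids)], out / "breeds_qc.tsv"
        )

        stage("tree")
        if config.tree == "build-nj":
            dist = tree_model.k2p_distance_matrix(
                aln.records, min_shared=config.min_shared_sites
            )
            tree = tree_model.nj_tree(dist)
            summary["tree_source"] = "internal-nj"
        else:
            tree = tree_model.read_newick(config.tree)
            summary["tree_source"] = str(config.tree)
            logger.info("external tree supplied; NJ stage skipped")
        if config.outgroup:
            tree = tree_model.root_with_outgroup(tree, config.outgroup)
        tree_model.write_newick(tree, out / "tree.nwk")

        breed_of = dict(zip(breed_table["id"], breed_table["breed"]))

        if config.haplogroup_references:
            stage("haplogroups")
            refs = tree_model.read_reference_labels(config.haplogroup_references)
            assignment = tree_model.assign_haplogroups(tree, refs)
            assignment.to_frame().to_csv(
                out / "haplogroups.tsv", sep="\t", index=False
            )
            summarize_haplogroups(assignment, breed_table).to_csv(
                out / "haplogroup_summary.tsv", sep="\t"
            )
            summary["haplogroup_counts"] = assignment.counts()

        stage("connections")
        grouping = _read_grouping(config.grouping) if config.grouping else {}
        matrices = {}
        for ktype in config.kinship_types:
            mat = kinship_core.connection_matrix(tree, breed_of, ktype)
            mat.to_tsv(out / f"connections_type{ktype}.tsv")
            matrices[ktype] = mat
            summary[f"type{ktype}_total"] = mat.total()
        if 2 in matrices:
            profiles = []
            for breed in matrices[2].breeds:
                prof = kinship_core.breed_profile(
                    matrices[2],
                    breed,
                    grouping=grouping,
                    retention_fraction=config.retention_fraction,
                )
                frame = prof.to_frame()
                frame.insert(0, "focal", breed)
                profiles.append(frame)
            pd.concat(profiles, ignore_index=True).to_csv(
                out / "profiles_type2.tsv", sep="\t", index=False
            )

        stage("fst")
        fst_aln, fst_table = popgen_fst.apply_population_filters(
            aln,
            breed_table,
            min_individuals=config.min_individuals,
            max_missing_frac=config.max_missing_frac,
        )
        summary["fst_populations"] = fst_table["breed"].nunique()
        fst = popgen_fst.phi_st_matrix(fst_aln, fst_table)
        fst.to_tsv(out / "fst.tsv")

        stage("ordination")
        fst_d = fst.values.clip(lower=0.0)
        np.fill_diagonal(fst_d.values, 0.0)
        if len(fst.populations) >= 4:
            result = ordination.nmds(
                fst_d,
                n_restarts=config.nmds_restarts,
                seed=stage_seeds[3],
            )
            result.to_tsv(out / "nmds_coords.tsv")
            summary["nmds_stress"] = result.stress
        ordination.upgma(fst_d).to_newick(out / "dendrogram_fst.nwk")
        if 2 in matrices and len(matrices[2].breeds) >= 3:
            prof_d = kinship_core.profile_distance_matrix(
                matrices[2], metric="correlation"
            )
            ordination.upgma(prof_d).to_newick(out / "dendrogram_profiles.nwk")

        with open(out / "summary.json", "w", encoding="utf-8") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
    except Exception:
        logger.exception("pipeline failed at stage %r", summary["stages"][-1])
        raise
    finally:
        root_logger.removeHandler(handler)
        handler.close()
    return out
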