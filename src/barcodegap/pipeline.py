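"""End-to-end orchestration: QC -> distances -> haplotypes -> tree ->
network -> delimitation, with every intermediate artifact on disk.

The stage order is fixed; a failure in any stage halts the run with a
stage-tagged error.  All randomness (distance SEs, tree bootstrap)
derives from the single config seed, so a rerun with the same config is
byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import delimit as delimit_mod
from . import distances, haplotypes, njtree, parsnet, seqio
from .errors import BarcodeGapError, ConfigError

logger = logging.getLogger("barcodegap")


@dataclass
class RunConfig:
    alignment: str
    metadata: str
    outdir: str
    seed: int
    deletion_mode: str = "complete"
    cutoff: float = 0.02
    support_min: float = 80.0
    bootstrap: int = 1000
    se_reps: int = 1000
    connection_limit: str | int = "auto"   # "auto", or a fixed integer
    parsimony_confidence: float = 0.95
    ten_x_mode: str = "group"
    cluster_method: str = "single"
    genetic_code: str | int = "vertebrate_mitochondrial"
    frame: str | int = "auto"

    def validate(self) -> None:
        if self.cutoff <= 0:
            raise ConfigError("cutoff must be positive")
        if not 0 <= self.support_min <= 100:
            raise ConfigError("support_min must be in [0, 100]")
        if self.bootstrap < 0 or self.se_reps < 0:
            raise ConfigError("replicate counts must be >= 0")
        if self.deletion_mode not in ("complete", "pairwise"):
            raise ConfigError(f"unknown deletion mode {self.deletion_mode!r}")
        if self.connection_limit != "auto":
            if int(self.connection_limit) < 1:
                raise ConfigError("fixed connection limit must be >= 1")
        if self.seed is None:
            raise ConfigError("seed is required")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except BarcodeGapError as e:
                raise type(e)(f"[stage {name}] {e}") from e

        return wrapped

    return deco


def run(config: RunConfig) -> delimit_mod.DelimitationReport:
    """Execute the full pipeline and write all artifacts to ``outdir``."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")

    # independent child seeds for the two stochastic stages
    ss = np.random.SeedSequence(config.seed)
    se_seed, boot_seed = [int(s) for s in ss.generate_state(2, dtype=np.uint32) % (2**31)]

    logger.info("stage qc: reading inputs")
    aln = _stage("qc")(seqio.read_alignment)(config.alignment)
    records = _stage("qc")(seqio.read_metadata)(config.metadata)
    species = _stage("qc")(seqio.cross_reference)(aln, records)
    qc = _stage("qc")(seqio.qc_screen)(aln, code=config.genetic_code, frame=config.frame)
    qc.write_tsv(outdir / "qc.tsv")
    logger.info(
        "stage qc: n=%d specimens, L=%d sites, frame=%d, clean=%s",
        aln.n, aln.L, qc.frame, qc.all_clean,
    )

    logger.info("stage dist: K2P distances (%s deletion, %d SE reps)",
                config.deletion_mode, config.se_reps)
    dm = _stage("dist")(distances.distance_matrix)(
        aln, deletion_mode=config.deletion_mode,
        se_reps=config.se_reps, seed=se_seed,
    )
    dm.write_tsv(outdir / "distances.tsv")
    dm.write_phylip(outdir / "distances.phy")
    gap = distances.gap_summary(dm, records)
    group = distances.group_mean_matrix(dm, species)
    group.write_tsv(outdir / "species_mean_distances.tsv")

    logger.info("stage hap: collapsing haplotypes")
    haps = _stage("hap")(haplotypes.collapse)(aln)
    stats = haplotypes.site_stats(aln)
    haps.write_tsv(outdir / "haplotypes.tsv", species=species)
    stats.write_tsv(outdir / "site_stats.tsv")
    logger.info(
        "stage hap: %d haplotypes, %d variable sites (%d parsimony-informative)",
        haps.k, stats.n_variable, stats.n_parsimony_informative,
    )

    tree = None
    if aln.n >= 3:
        logger.info("stage tree: NJ with B=%d bootstrap replicates", config.bootstrap)
        if config.bootstrap > 0:
            tree = _stage("tree")(njtree.bootstrap)(
                aln, deletion_mode=config.deletion_mode,
                B=config.bootstrap, seed=boot_seed,
            )
        else:
            tree = _stage("tree")(njtree.nj)(dm)
        tree.write_newick(outdir / "nj_tree.nwk")

    if config.connection_limit == "auto":
        jstar = parsnet.parsimony_limit(aln.L, p=config.parsimony_confidence)
    else:
        jstar = int(config.connection_limit)
    logger.info("stage net: connection limit j*=%d", jstar)
    net = _stage("net")(parsnet.build_network)(haps, jstar)
    net.write_edges_tsv(outdir / "network_edges.tsv")
    net.write_components_tsv(outdir / "network_components.tsv")
    net.write_graphml(outdir / "network.graphml")

    logger.info("stage delimit: assembling report")
    report = _stage("delimit")(delimit_mod.assemble_report)(
        records=records, dm=dm, haps=haps, net=net, tree=tree, gap=gap,
        t=config.cutoff, support_min=config.support_min,
        ten_x_mode=config.ten_x_mode, cluster_method=config.cluster_method,
    )
    report.params["seed"] = config.seed
    report.params["bootstrap_replicates"] = config.bootstrap
    report.params["se_replicates"] = config.se_reps
    report.write_json(outdir / "report.json")
    report.write_tsv(outdir / "report.tsv")
    logger.info("stage delimit: flagged species: %s", report.flagged_species)
    return report
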