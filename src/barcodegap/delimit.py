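"""Rule-based flagging of deeply divergent conspecific lineages.

Two classic heuristics drive the report:

* the 2% cutoff — specimens of one nominal species separated by >= 2%
  K2P distance are unlikely to be conspecific; lineages are the
  single-linkage clusters obtained by chaining pairs closer than the
  cutoff (complete linkage available as an option);
* the 10X rule — a species is flagged when its maximum conspecific
  divergence reaches 10 times a reference mean intraspecific
  variability (whole-study by default, per-species as an option).

These are cross-checked against the haplotype network (a species whose
haplotypes fall in more than one independent subnetwork) and against
bootstrap-supported subclades in the NJ tree.  The headline
"deep conspecific divergence" flag is cutoff OR network split — the two
lines of evidence the barcode literature treats as decisive.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .distances import DistanceMatrix, GapSummary
from .errors import AssemblyError, ConfigError, LabelingError
from .haplotypes import HaplotypeSet
from .njtree import SupportTree
from .parsnet import HaplotypeNetwork
from .seqio import SpecimenRecord


def threshold_clusters(
    dm: DistanceMatrix,
    ids: Sequence[str] | None = None,
    t: float = 0.02,
    method: str = "single",
) -> list[list[str]]:
    """Partition specimens by distance threshold.

    ``single`` (default): two specimens share a cluster iff connected by
    a chain of pairs each strictly below ``t`` — the transitive closure
    of the pairwise 2%-rule.  ``complete``: scipy complete-linkage cut at
    ``t``.  Clusters are returned in order of their first specimen, each
    sorted by appearance in ``ids``.
    """
    if t <= 0:
        raise ConfigError("threshold t must be positive")
    ids = list(dm.ids) if ids is None else list(ids)
    idx = [dm.index(i) for i in ids]
    sub = dm.d[np.ix_(idx, idx)]
    n = len(ids)
    if n == 1:
        return [[ids[0]]]
    if method == "single":
        parent = list(range(n))

        def find(a):
            while parent[a] != a:
                parent[a] = parent[parent[a]]
                a = parent[a]
            return a

        for i in range(n):
            for j in range(i + 1, n):
                if sub[i, j] < t:
                    ri, rj = find(i), find(j)
                    if ri != rj:
                        parent[rj] = ri
        assign = [find(i) for i in range(n)]
    elif method == "complete":
        Z = linkage(squareform(sub, checks=False), method="complete")
        assign = fcluster(Z, t=t, criterion="distance")
    else:
        raise ConfigError(f"unknown clustering method {method!r}")
    clusters: dict[int, list[str]] = {}
    order: list[int] = []
    for k, a in enumerate(assign):
        if a not in clusters:
            clusters[a] = []
            order.append(a)
        clusters[a].append(ids[k])
    return [clusters[a] for a in order]


def ten_x_flag(
    species_mean_intra: float,
    group_mean_intra: float,
    observed_max: float,
    mode: str = "group",
) -> bool:
    """10X rule: does the species' maximum conspecific divergence reach
    10 times the reference mean intraspecific variability?

    ``mode="group"`` (default) uses the whole-study mean; ``"species"``
    uses the species' own mean.  A zero reference with positive observed
    divergence flags true (with a degenerate-reference warning).
    """
    if mode not in ("group", "species"):
        raise ConfigError(f"unknown 10X mode {mode!r}")
    ref = group_mean_intra if mode == "group" else species_mean_intra
    if ref < 0:
        raise ConfigError("reference mean must be >= 0")
    if ref == 0:
        if observed_max > 0:
            warnings.warn("10X rule applied with zero reference mean")
            return True
        return False
    return observed_max >= 10.0 * ref


@dataclass
class SpeciesReport:
    species: str
    n_specimens: int
    n_haplotypes: int
    conspecific_mean_pct: Optional[float]
    conspecific_max_pct: Optional[float]
    lineages: dict[str, list[str]]                    # label -> member specimen ids
    lineage_sites: dict[str, list[str]]               # label -> sampling sites
    singleton_lineages: list[str]                     # labels backed by one individual
    flags: dict[str, bool]
    between_lineage_mean_pct: dict[str, float]        # "L1|L2" -> mean %
    n_network_units: int

    @property
    def deep_divergence(self) -> bool:
        return self.flags["cutoff_2pct"] or self.flags["network_split"]


@dataclass
class DelimitationReport:
    species_reports: list[SpeciesReport]
    gap: GapSummary
    shallow_pairs: list[tuple[str, str, float]]       # between-species mean < t (%)
    params: dict

    @property
    def flagged_species(self) -> list[str]:
        return [r.species for r in self.species_reports if r.deep_divergence]

    def to_dict(self) -> dict:
        def _r(x):
            return None if x is None else round(float(x), 6)

        return {
            "params": self.params,
            "gap_summary": {
                "conspecific": {
                    "min": _r(self.gap.conspecific.min),
                    "mean": _r(self.gap.conspecific.mean),
                    "max": _r(self.gap.conspecific.max),
                    "se": _r(self.gap.conspecific.se),
                    "n_pairs": self.gap.conspecific.n_pairs,
                },
                "congeneric": {
                    "min": _r(self.gap.congeneric.min),
                    "mean": _r(self.gap.congeneric.mean),
                    "max": _r(self.gap.congeneric.max),
                    "se": _r(self.gap.congeneric.se),
                    "n_pairs": self.gap.congeneric.n_pairs,
                },
            },
            "shallow_interspecific_pairs": [
                {"species_a": a, "species_b": b, "mean_pct": _r(v)}
                for a, b, v in self.shallow_pairs
            ],
            "species": [
                {
                    "species": r.species,
                    "n_specimens": r.n_specimens,
                    "n_haplotypes": r.n_haplotypes,
                    "conspecific_mean_pct": _r(r.conspecific_mean_pct),
                    "conspecific_max_pct": _r(r.conspecific_max_pct),
                    "lineages": {k: sorted(v) for k, v in r.lineages.items()},
                    "lineage_sites": {k: sorted(set(v)) for k, v in r.lineage_sites.items()},
                    "singleton_lineages": sorted(r.singleton_lineages),
                    "flags": r.flags,
                    "deep_divergence": r.deep_divergence,
                    "between_lineage_mean_pct": {
                        k: _r(v) for k, v in r.between_lineage_mean_pct.items()
                    },
                    "n_network_units": r.n_network_units,
                }
                for r in self.species_reports
            ],
            "flagged_species": self.flagged_species,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    def write_json(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json() + "\n")

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(
                "species\tn_specimens\tn_haplotypes\tn_lineages\t"
                "conspecific_mean_pct\tconspecific_max_pct\t"
                "cutoff_2pct\tten_x\tnetwork_split\tsupported_subclades\t"
                "deep_divergence\tlineages\n"
            )
            for r in self.species_reports:
                lin = ";".join(
                    f"{lab}:{','.join(sorted(mem))}" for lab, mem in r.lineages.items()
                )
                mean = "" if r.conspecific_mean_pct is None else f"{r.conspecific_mean_pct:.4f}"
                mx = "" if r.conspecific_max_pct is None else f"{r.conspecific_max_pct:.4f}"
                fh.write(
                    f"{r.species}\t{r.n_specimens}\t{r.n_haplotypes}\t{len(r.lineages)}\t"
                    f"{mean}\t{mx}\t"
                    f"{r.flags['cutoff_2pct']}\t{r.flags['ten_x']}\t"
                    f"{r.flags['network_split']}\t{r.flags['supported_subclades']}\t"
                    f"{r.deep_divergence}\t{lin}\n"
                )


def _lineage_labels(species: str, clusters: list[list[str]]) -> list[str]:
    """Labels: species initial (uppercased) + rank by cluster size
    (largest first; ties by first specimen id)."""
    initial = species.strip()[0].upper() if species.strip() else "X"
    ranked = sorted(clusters, key=lambda c: (-len(c), sorted(c)[0]))
    labels = [None] * len(clusters)
    for rank, cl in enumerate(ranked, start=1):
        labels[clusters.index(cl)] = f"{initial}{rank}"
    return labels


def assemble_report(
    records: Sequence[SpecimenRecord],
    dm: DistanceMatrix,
    haps: HaplotypeSet,
    net: HaplotypeNetwork,
    tree: SupportTree | None,
    gap: GapSummary,
    t: float = 0.02,
    support_min: float = 80.0,
    ten_x_mode: str = "group",
    cluster_method: str = "single",
) -> DelimitationReport:
    """Combine every line of evidence into the per-species report.

    Lineages are the threshold clusters; the network and (when a
    bootstrapped tree is supplied) supported subclades are recorded as
    independent flags.  All inputs must cover the same specimen set.
    """
    rec_ids = {r.specimen_id for r in records}
    if rec_ids != set(dm.ids):
        raise AssemblyError("metadata and distance matrix cover different specimens")
    hap_ids = {sid for mem in haps.members for sid in mem}
    if hap_ids != set(dm.ids):
        raise AssemblyError("haplotype set and distance matrix cover different specimens")

    species_of = {r.specimen_id: r.species for r in records}
    site_of = {r.specimen_id: r.site for r in records}
    by_species: dict[str, list[str]] = {}
    for sid in dm.ids:
        by_species.setdefault(species_of[sid], []).append(sid)

    hap_species = haps.species_of(species_of)
    hap_label_species: dict[str, str] = {}
    for h, sps in enumerate(hap_species):
        # haplotypes are species-private in barcode data; if not, attribute
        # the haplotype to each species when counting units below
        hap_label_species[haps.ids[h]] = sorted(sps)[0]
    comp_of = net.component_of()
    units: dict[str, set] = {sp: set() for sp in by_species}
    for h, sps in enumerate(hap_species):
        for sp in sps:
            units.setdefault(sp, set()).add(comp_of[haps.ids[h]])

    # whole-study mean intraspecific variability for the 10X rule
    intra_all: list[float] = []
    intra_by_species: dict[str, np.ndarray] = {}
    for sp, members in by_species.items():
        idx = [dm.index(i) for i in members]
        sub = dm.d[np.ix_(idx, idx)]
        iu = np.triu_indices(len(members), k=1)
        vals = sub[iu]
        intra_by_species[sp] = vals
        intra_all.extend(vals.tolist())
    study_mean_intra = float(np.mean(intra_all)) if intra_all else 0.0

    tree_bips = None
    if tree is not None:
        if set(tree.leaves()) != set(dm.ids):
            raise AssemblyError("tree and distance matrix cover different specimens")
        tree_bips = tree.bipartitions()

    reports = []
    for sp, members in by_species.items():
        vals = intra_by_species[sp]
        clusters = threshold_clusters(dm, ids=members, t=t, method=cluster_method)
        labels = _lineage_labels(sp, clusters)
        lineages = dict(zip(labels, clusters))
        sp_haps = {
            haps.ids[h] for h, mem in enumerate(haps.members)
            if any(species_of[s] == sp for s in mem)
        }

        sp_mean = float(vals.mean()) if vals.size else None
        sp_max = float(vals.max()) if vals.size else None

        supported = False
        if tree_bips is not None and len(members) >= 3:
            mset = set(members)
            for side, clade in tree_bips.items():
                for s in (set(side), set(dm.ids) - set(side)):
                    if (
                        s < mset
                        and len(s) >= 2
                        and clade.support is not None
                        and clade.support >= support_min
                    ):
                        supported = True

        flags = {
            "cutoff_2pct": len(clusters) > 1,
            "ten_x": ten_x_flag(
                sp_mean or 0.0, study_mean_intra, sp_max or 0.0, mode=ten_x_mode
            ) if vals.size else False,
            "network_split": len(units[sp]) > 1,
            "supported_subclades": supported,
        }

        between = {}
        if len(lineages) > 1:
            labs = list(lineages)
            for a in range(len(labs)):
                for b in range(a + 1, len(labs)):
                    ia = [dm.index(x) for x in lineages[labs[a]]]
                    ib = [dm.index(x) for x in lineages[labs[b]]]
                    between[f"{labs[a]}|{labs[b]}"] = (
                        float(dm.d[np.ix_(ia, ib)].mean()) * 100.0
                    )

        reports.append(
            SpeciesReport(
                species=sp,
                n_specimens=len(members),
                n_haplotypes=len(sp_haps),
                conspecific_mean_pct=None if sp_mean is None else sp_mean * 100.0,
                conspecific_max_pct=None if sp_max is None else sp_max * 100.0,
                lineages=lineages,
                lineage_sites={
                    lab: [site_of[s] for s in mem] for lab, mem in lineages.items()
                },
                singleton_lineages=[lab for lab, mem in lineages.items() if len(mem) == 1],
                flags=flags,
                between_lineage_mean_pct=between,
                n_network_units=len(units[sp]),
            )
        )
    reports.sort(key=lambda r: r.species)

    # shallow interspecific warning: species pairs whose between-species
    # mean is below the cutoff
    shallow = []
    sp_list = sorted(by_species)
    for a in range(len(sp_list)):
        for b in range(a + 1, len(sp_list)):
            ia = [dm.index(x) for x in by_species[sp_list[a]]]
            ib = [dm.index(x) for x in by_species[sp_list[b]]]
            mean_ab = float(dm.d[np.ix_(ia, ib)].mean())
            if mean_ab < t:
                shallow.append((sp_list[a], sp_list[b], mean_ab * 100.0))

    params = {
        "cutoff": t,
        "support_min": support_min,
        "ten_x_mode": ten_x_mode,
        "cluster_method": cluster_method,
        "connection_limit": net.connection_limit,
        "study_mean_intraspecific_pct": round(study_mean_intra * 100.0, 6),
    }
    return DelimitationReport(
        species_reports=reports, gap=gap, shallow_pairs=shallow, params=params
    )
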