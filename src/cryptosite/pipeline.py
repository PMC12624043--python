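"""End-to-end orchestration of the cryptic-phosphosite workflow.

``run_scan`` performs the static stages: map PTM sites onto structures,
apply the model-confidence gate, compute RSA and classify sites as cryptic
or not.  ``run_full`` continues with the dynamical stages: prune
low-confidence segments, merge contacting segments into entries, drop small
entries, recompute RSA on the pruned entries, decompose each entry into
quasi-rigid domains and apply the intra-domain-contact filter.  Every input
site ends with exactly one terminal status, and the per-stage counts always
sum back to the input count.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from . import accessibility, dynamic_filter
from .accessibility import SasaParams, Thresholds
from .errors import DataError
from .structio import SiteRecord, Structure

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All tunables in one place; defaults are the canonical thresholds
    (RSA 0.15, pLDDT 65, 40-residue entries, 5 A / 5-pair merging, Pidc 0.80,
    7.5 A elastic-network cutoff, 10 modes)."""

    rsa_cryptic: float = 0.15
    plddt_min: float = 65.0
    min_domain_size: int = 40
    merge_dist: float = 5.0
    merge_min_pairs: int = 5
    pidc_min: float = 0.80
    pidc_radius: float = 6.0
    enm_cutoff: float = 7.5
    n_modes: int = 10
    k_max: int = 10
    seed: int = 0
    sasa: SasaParams = field(default_factory=SasaParams)

    @property
    def thresholds(self) -> Thresholds:
        return Thresholds(rsa_cryptic=self.rsa_cryptic, plddt_min=self.plddt_min)

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["sasa"].pop("radii_table", None)
        return json.dumps(d, indent=2, sort_keys=True)


@dataclass
class ScanResult:
    sites: list[SiteRecord]
    histogram: pd.DataFrame
    cryptic_fraction: dict[str, float]
    status_counts: dict[str, int]


@dataclass
class FullResult:
    sites: list[SiteRecord]
    decompositions: dict[str, list[tuple[dynamic_filter.Entry,
                                         dynamic_filter.RigidDecomposition]]]
    pidc: dict[tuple[str, int], dynamic_filter.PidcResult]
    waterfall: dict[str, int]


def _status_counts(sites: list[SiteRecord]) -> dict[str, int]:
    return dict(Counter(s.status for s in sites))


def run_scan(structures: dict[str, Structure], sites: list[SiteRecord],
             config: PipelineConfig | None = None) -> ScanResult:
    """Static stages: map -> confidence filter -> RSA -> classify."""
    config = config or PipelineConfig()
    by_accession: dict[str, list[SiteRecord]] = {}
    for s in sites:
        by_accession.setdefault(s.accession, []).append(s)
    for accession, group in by_accession.items():
        structure = structures.get(accession)
        if structure is None:
            for s in group:
                s.mark("excluded:no_structure")
            logger.info("no structure for %s: %d sites excluded", accession, len(group))
            continue
        accessibility.map_ptm_sites(group, structure, config.sasa)
        for s in group:
            if s.status == "mapped":
                accessibility.classify_site(s, config.thresholds)
    histogram, fractions = accessibility.rsa_distribution(
        sites, rsa_cryptic=config.rsa_cryptic)
    return ScanResult(sites=sites, histogram=histogram,
                      cryptic_fraction=fractions,
                      status_counts=_status_counts(sites))


def run_full(structures: dict[str, Structure], sites: list[SiteRecord],
             config: PipelineConfig | None = None) -> FullResult:
    """Static scan followed by the dynamical filtering stages."""
    config = config or PipelineConfig()
    scan = run_scan(structures, sites, config)
    waterfall = {"input": len(sites), "after_scan_cryptic":
                 sum(1 for s in sites if s.status == "cryptic")}
    decompositions: dict[str, list] = {}
    pidc_results: dict[tuple[str, int], dynamic_filter.PidcResult] = {}

    for accession, structure in structures.items():
        candidates = [s for s in sites
                      if s.accession == accession and s.status == "cryptic"]
        segments = dynamic_filter.prune_low_confidence(structure, config.plddt_min)
        if not segments:
            for s in candidates:
                s.mark("excluded:small_domain")
            continue
        entries = dynamic_filter.merge_entries(
            segments, accession, config.merge_dist, config.merge_min_pairs)
        entries, _ = dynamic_filter.size_gate(entries, candidates,
                                              config.min_domain_size)
        decompositions[accession] = []
        for entry in entries:
            in_entry = [s for s in candidates if s.position in entry.positions]
            dynamic_filter.refilter_rsa(entry, in_entry, config.thresholds,
                                        config.sasa)
            still = [s for s in in_entry if s.status == "cryptic"]
            if not still:
                continue
            modes = dynamic_filter.enm_modes(entry, config.enm_cutoff,
                                             config.n_modes)
            decomposition = dynamic_filter.quasi_rigid_decompose(
                entry, modes, config.k_max, config.seed)
            decompositions[accession].append((entry, decomposition))
            results = dynamic_filter.apply_dynamic_filter(
                still, entry, decomposition, config.pidc_min, config.pidc_radius)
            for pos, res in results.items():
                pidc_results[(accession, pos)] = res

    waterfall.update(_status_counts(sites))
    waterfall["final_cryptic"] = sum(1 for s in sites if s.status == "cryptic")
    return FullResult(sites=sites, decompositions=decompositions,
                      pidc=pidc_results, waterfall=waterfall)


def sites_table(sites: list[SiteRecord],
                pidc: dict[tuple[str, int], dynamic_filter.PidcResult] | None = None,
                ) -> pd.DataFrame:
    """Tabular export of site records (one row per site)."""
    rows = []
    for s in sites:
        row = {"accession": s.accession, "position": s.position, "aa": s.aa,
               "ptm_class": s.ptm_class, "sasa": s.sasa, "rsa": s.rsa,
               "plddt": s.plddt, "status": s.status,
               "provenance": ">".join(s.history)}
        if pidc is not None:
            res = pidc.get((s.accession, s.position))
            row["n_neighbors"] = res.n_neighbors if res else None
            row["pidc"] = res.pidc if res else None
        rows.append(row)
    return pd.DataFrame(rows)


def domain_table(decompositions: dict[str, list]) -> pd.DataFrame:
    """Per-residue quasi-rigid domain labels for every decomposed entry."""
    rows = []
    for accession, pairs in decompositions.items():
        for entry_id, (entry, decomposition) in enumerate(pairs):
            for pos, dom in sorted(decomposition.labels.items()):
                rows.append({"accession": accession, "entry": entry_id,
                             "position": pos, "domain_id": dom,
                             "chosen_k": decomposition.chosen_k,
                             "quality": decomposition.quality[decomposition.chosen_k]})
    return pd.DataFrame(rows)


def check_waterfall(result: FullResult) -> None:
    """Every site must carry exactly one terminal status summing to the input."""
    statuses = _status_counts(result.sites)
    if sum(statuses.values()) != len(result.sites):
        raise DataError("status counts do not sum to the input site count")
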