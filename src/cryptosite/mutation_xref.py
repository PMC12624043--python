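"""Cross-referencing cryptic phosphosites with somatic-mutation catalogs.

Raw screen rows (COSMIC / PTMVar style) are preprocessed by dropping
negative screens and collapsing identical mutations with a sample count.
A substitution is *phosphomimetic* when it replaces a phosphorylatable
residue (S, T or Y) with an aspartate or glutamate, whose charge mimics the
phosphate group.  Cross-referencing joins mutations onto cryptic sites by
(accession, position), rejecting hits whose reference residue disagrees
with the site.
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError
from .structio import SiteRecord

logger = logging.getLogger(__name__)

#: accepts "p.S417E" and bare "S417E"
_PROTEIN_CHANGE_RE = re.compile(r"^(?:p\.)?([A-Z])(\d+)([A-Z])$")

PHOSPHO_ACCEPTORS = frozenset("STY")
PHOSPHOMIMETIC_TARGETS = frozenset("DE")


@dataclass(frozen=True)
class MutationRecord:
    accession: str
    gene: str
    position: int
    aa_from: str
    aa_to: str
    cds_change: str
    count: int
    screen_status: str = "positive"
    annotation: str = ""

    def __post_init__(self) -> None:
        if self.aa_from == self.aa_to:
            raise DataError(f"silent change {self.aa_from}{self.position}{self.aa_to}")
        if self.position < 1 or self.count < 1:
            raise DataError("position and count must be >= 1")


def parse_protein_change(text: str) -> tuple[str, int, str] | None:
    m = _PROTEIN_CHANGE_RE.match(text.strip())
    if m is None:
        return None
    return m.group(1), int(m.group(2)), m.group(3)


def is_phosphomimetic(aa_from: str, aa_to: str) -> bool:
    """True iff a phospho-acceptor (S/T/Y) is replaced by D or E."""
    return aa_from in PHOSPHO_ACCEPTORS and aa_to in PHOSPHOMIMETIC_TARGETS


def preprocess_mutations(rows: pd.DataFrame | list[dict]) -> list[MutationRecord]:
    """Drop negative screens and collapse identical mutations with counts.

    Expects columns/keys: accession, gene, protein_change (``p.S417E``
    dialect), cds_change, screen_status, annotation (the last two optional).
    Identity for collapsing is (accession, position, aa_from, aa_to,
    cds_change); the resulting count is the row multiplicity, so counts over
    collapsed records always sum to the number of positive input rows.
    """
    if isinstance(rows, pd.DataFrame):
        rows = rows.to_dict("records")
    counter: Counter = Counter()
    meta: dict[tuple, dict] = {}
    n_skipped = 0
    for row in rows:
        if str(row.get("screen_status", "positive")).lower() == "negative":
            continue
        parsed = parse_protein_change(str(row.get("protein_change", "")))
        if parsed is None:
            n_skipped += 1
            logger.warning("skipping unparseable protein change %r", row.get("protein_change"))
            continue
        aa_from, position, aa_to = parsed
        key = (str(row["accession"]), position, aa_from, aa_to,
               str(row.get("cds_change", "")))
        counter[key] += 1
        meta.setdefault(key, {"gene": str(row.get("gene", "")),
                              "annotation": str(row.get("annotation", ""))})
    records = []
    for key, count in sorted(counter.items()):
        accession, position, aa_from, aa_to, cds = key
        records.append(MutationRecord(
            accession=accession, gene=meta[key]["gene"], position=position,
            aa_from=aa_from, aa_to=aa_to, cds_change=cds, count=count,
            screen_status="positive", annotation=meta[key]["annotation"]))
    if n_skipped:
        logger.info("preprocess_mutations: %d rows skipped", n_skipped)
    return records


def cross_reference(cryptic_sites: list[SiteRecord],
                    mutations: list[MutationRecord]) -> tuple[pd.DataFrame, dict]:
    """Inner join of mutations onto cryptic sites by (accession, position).

    A hit whose reference residue differs from the site's residue is
    rejected and logged.  Returns the hit table and summary counts (total
    hits, phosphomimetic hits, hits carrying a cancer annotation).
    """
    site_index = {(s.accession, s.position): s for s in cryptic_sites}
    rows = []
    n_rejected = 0
    for mut in mutations:
        site = site_index.get((mut.accession, mut.position))
        if site is None:
            continue
        if mut.aa_from != site.aa:
            n_rejected += 1
            logger.warning("rejecting hit %s:%d: mutation says %s, site says %s",
                           mut.accession, mut.position, mut.aa_from, site.aa)
            continue
        rows.append({
            "accession": mut.accession, "gene": mut.gene, "position": mut.position,
            "aa_from": mut.aa_from, "aa_to": mut.aa_to, "cds_change": mut.cds_change,
            "count": mut.count, "annotation": mut.annotation,
            "phosphomimetic": is_phosphomimetic(mut.aa_from, mut.aa_to),
            "cancer_related": "cancer" in mut.annotation.lower(),
        })
    hits = pd.DataFrame(rows, columns=[
        "accession", "gene", "position", "aa_from", "aa_to", "cds_change",
        "count", "annotation", "phosphomimetic", "cancer_related"])
    summary = {
        "total_hits": len(hits),
        "phosphomimetic_hits": int(hits["phosphomimetic"].sum()) if len(hits) else 0,
        "cancer_hits": int(hits["cancer_related"].sum()) if len(hits) else 0,
        "rejected_mismatches": n_rejected,
    }
    return hits, summary


def two_proportion_z(hits1: int, n1: int, hits2: int, n2: int) -> dict:
    """Two-proportion z statistic for equal disease-mutation rates.

    Used to check that cryptic and non-cryptic sites carry disease
    mutations at the same rate.
    """
    if min(n1, n2) == 0:
        raise DataError("both groups must be non-empty")
    p1, p2 = hits1 / n1, hits2 / n2
    pooled = (hits1 + hits2) / (n1 + n2)
    se = np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    z = 0.0 if se == 0 else (p1 - p2) / se
    return {
        "proportion_1": p1, "proportion_2": p2, "z": float(z),
        "p_value": float(2 * stats.norm.sf(abs(z))),
    }
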