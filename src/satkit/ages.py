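"""Taxonomic presence filtering and MRCA-based minimal-age estimation.

A satDNA family shared by several taxa must be at least as old as the most
recent common ancestor of those taxa on a time-calibrated tree, so the MRCA's
node age is the family's *minimal* age. Presence requires the best BLAST-style
query coverage of the consensus to strictly exceed the threshold ("exceeded
50% of the monomer sequence" reads as a strict inequality). A family found
only in the focal taxon has no informative MRCA: its minimal age is 0 and its
upper bound is the dated emergence of a configured ancestral clade.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from satkit.trees import DatedTree

logger = logging.getLogger("satkit")


@dataclass
class PresenceMatrix:
    """Best query coverage per taxon x family, plus the presence threshold."""

    coverage: pd.DataFrame  # index: taxon, columns: family, values in [0, 1]
    threshold: float = 0.5

    def qualifying_taxa(self, family: str) -> list[str]:
        if family not in self.coverage.columns:
            return []
        col = self.coverage[family].dropna()
        return sorted(col.index[col > self.threshold])  # strict: "exceeded"

    @property
    def families(self) -> list[str]:
        return list(self.coverage.columns)


@dataclass
class AgeEstimate:
    family_id: str
    qualifying_taxa: list[str]
    mrca_node: str | None
    minimal_age: float
    upper_bound: float | None

    def __post_init__(self) -> None:
        if self.upper_bound is not None and self.minimal_age > self.upper_bound:
            raise ValueError("minimal age exceeds upper bound")


def filter_presence(
    hits: pd.DataFrame,
    coverage_threshold: float = 0.5,
    focal_taxon: str | None = None,
) -> PresenceMatrix:
    """Coverage-filtered presence from a hit table (taxon, family, query_coverage).

    The best coverage per taxon x family is kept; a taxon qualifies for a
    family iff that coverage strictly exceeds the threshold. The focal taxon,
    if named, is pinned at coverage 1 for every family (its own satellitome).
    """
    required = {"taxon", "family", "query_coverage"}
    if not required <= set(hits.columns):
        raise ValueError(f"hit table must have columns {sorted(required)}")
    cov = hits["query_coverage"]
    if len(cov) and (cov.min() < 0 or cov.max() > 1):
        raise ValueError("query coverage must lie in [0, 1]")
    if len(hits):
        table = hits.pivot_table(index="taxon", columns="family", values="query_coverage", aggfunc="max")
    else:
        table = pd.DataFrame()
    if focal_taxon is not None:
        for fam in table.columns:
            table.loc[focal_taxon, fam] = 1.0
        if table.empty:
            table = pd.DataFrame(index=pd.Index([focal_taxon], name="taxon"))
    return PresenceMatrix(coverage=table, threshold=coverage_threshold)


def collapse_to_rank(hits: pd.DataFrame, taxon_to_rank: dict[str, str]) -> pd.DataFrame:
    """Map species-level hits up to a coarser rank (e.g. order).

    Unmapped taxa are dropped with a log line; coverage per rank is the best
    coverage among its species.
    """
    out = hits.copy()
    out["taxon"] = out["taxon"].map(taxon_to_rank)
    dropped = out["taxon"].isna()
    if dropped.any():
        logger.info("collapse_to_rank: dropping %d hits with unmapped taxa", int(dropped.sum()))
        out = out[~dropped]
    return (
        out.groupby(["taxon", "family"], as_index=False)["query_coverage"].max()
    )


def minimal_age(
    presence: PresenceMatrix,
    tree: DatedTree,
    family: str,
    focal_taxon: str,
    clade_age_bound: float | None = None,
) -> AgeEstimate:
    """Minimal age of a family: age of the MRCA of its qualifying taxa.

    Equals the maximum pairwise divergence time among qualifying taxa and the
    focal taxon. ``clade_age_bound`` (MY) supplies the upper bound for
    families qualifying only in the focal taxon (the emergence age of the
    focal lineage's family-level clade).
    """
    taxa = set(presence.qualifying_taxa(family)) | {focal_taxon}
    known = set(tree.taxa)
    missing = sorted(taxa - known)
    if missing:
        raise ValueError(f"qualifying taxa missing from the dated tree: {missing}")
    if taxa == {focal_taxon}:
        return AgeEstimate(
            family_id=family,
            qualifying_taxa=sorted(taxa),
            mrca_node=None,
            minimal_age=0.0,
            upper_bound=clade_age_bound,
        )
    node = tree.mrca(sorted(taxa))
    return AgeEstimate(
        family_id=family,
        qualifying_taxa=sorted(taxa),
        mrca_node=node.label or ",".join(sorted(l.taxon.label for l in node.leaf_iter())),
        minimal_age=tree.node_age(node),
        upper_bound=None,
    )


def age_report(
    presence: PresenceMatrix,
    tree: DatedTree,
    focal_taxon: str,
    clade_age_bound: float | None = None,
) -> pd.DataFrame:
    """Minimal ages for every family in a presence matrix."""
    rows = []
    for fam in presence.families:
        est = minimal_age(presence, tree, fam, focal_taxon, clade_age_bound)
        rows.append(
            dict(
                family=fam,
                n_qualifying=len(est.qualifying_taxa),
                minimal_age=est.minimal_age,
                upper_bound=est.upper_bound,
                mrca=est.mrca_node,
            )
        )
    return pd.DataFrame(rows)
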