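"""Split merged BGC regions at user-defined boundary genes.

Gene-rich secondary-metabolite loci that lie close together on the
chromosome (canonically the plipastatin/fengycin and iturin clusters in
*Bacillus*) are often detected as a single merged region.  Given panels of
reference sequences for a left and a right boundary gene (e.g. *dacC* and
*yngH*), the region is cut into two regions so that both children retain
the intersection spanning the boundary genes.  Boundary genes are located
by pairwise alignment at configurable identity/coverage thresholds
(defaults 90%/90%).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

from ._align import identity_coverage, infix_identity, make_aligner
from .genome_model import BGCRegion, Gene

logger = logging.getLogger(__name__)


@dataclass
class SplitRule:
    """Homolog panels and thresholds for one split (e.g. dacC/yngH)."""

    left_gene_refs: list[str]
    right_gene_refs: list[str]
    min_identity: float = 0.90
    min_coverage: float = 0.90

    def __post_init__(self) -> None:
        if not self.left_gene_refs or not self.right_gene_refs:
            raise ValueError("both boundary-gene panels must be non-empty")
        for t in (self.min_identity, self.min_coverage):
            if not 0 < t <= 1:
                raise ValueError("thresholds must be in (0, 1]")


@dataclass(frozen=True)
class BoundaryHit:
    gene: Gene
    identity: float
    coverage: float
    which: str  # "left" | "right"


def locate_split_genes(region: BGCRegion, rule: SplitRule) -> list[BoundaryHit]:
    """Find boundary-gene homologs among the region's genes.

    Every gene is aligned (global, end gaps free on the longer sequence)
    against every panel reference; the best-scoring reference per gene is
    kept and reported as a hit when identity and coverage both reach the
    rule's thresholds.  Hits are sorted by genomic position.
    """
    aligner = make_aligner(free_end_gaps=True)
    hits: list[BoundaryHit] = []
    for which, panel in (("left", rule.left_gene_refs), ("right", rule.right_gene_refs)):
        for gene in region.genes:
            best = (0.0, 0.0)
            for ref in panel:
                # cheap pre-filter: skip clearly non-homologous genes
                if infix_identity(ref, gene.sequence) < rule.min_identity - 0.05:
                    continue
                ident, cov = identity_coverage(gene.sequence, ref, aligner)
                if (ident, cov) > best:
                    best = (ident, cov)
            if best[0] >= rule.min_identity and best[1] >= rule.min_coverage:
                hits.append(BoundaryHit(gene, best[0], best[1], which))
    hits.sort(key=lambda h: (h.gene.start, h.which))
    return hits


def split_region(
    region: BGCRegion, rule: SplitRule, overlap: bool = True
) -> list[BGCRegion]:
    """Cut a merged region in two at its boundary genes.

    Requires exactly one left hit L and one right hit R, with L upstream of
    R.  With ``overlap=True`` (default) child 1 spans region start to the
    end of R's gene and child 2 spans the start of L's gene to the region
    end, so both children contain the L..R intersection.  With
    ``overlap=False`` the cut is disjoint at the midpoint between L and R.
    Any other hit configuration returns the region unchanged with a logged
    reason.
    """
    hits = locate_split_genes(region, rule)
    left = [h for h in hits if h.which == "left"]
    right = [h for h in hits if h.which == "right"]
    if len(left) != 1 or len(right) != 1:
        if len(left) > 1 or len(right) > 1:
            logger.warning("%s: multiple boundary hits (left=%d right=%d); not split",
                           region.region_id, len(left), len(right))
        else:
            logger.info("%s: incomplete boundary hits (left=%d right=%d); not split",
                        region.region_id, len(left), len(right))
        return [region]
    L, R = left[0], right[0]
    if L.gene.start >= R.gene.start:
        logger.warning("%s: right boundary gene precedes left; not split", region.region_id)
        return [region]

    if overlap:
        a_start, a_end = region.start, R.gene.end
        b_start, b_end = L.gene.start, region.end
        if (a_start, a_end) == (region.start, region.end) or (b_start, b_end) == (
            region.start,
            region.end,
        ):
            # region already coincides with one child (e.g. it IS a child of a
            # previous split): cutting again would change nothing
            logger.info("%s: cut spans the whole region; not split", region.region_id)
            return [region]
    else:
        mid = (L.gene.end + R.gene.start) // 2
        a_start, a_end = region.start, mid
        b_start, b_end = mid, region.end

    def _child(suffix: str, start: int, end: int) -> BGCRegion:
        genes = [g for g in region.genes if g.start < end and g.end > start]
        return replace(region, region_id=f"{region.region_id}{suffix}",
                       start=start, end=end, genes=genes)

    return [_child(".1", a_start, a_end), _child(".2", b_start, b_end)]
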