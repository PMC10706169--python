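import numpy as np
import pytest

from brcacnv import CoverageTable, Panel, TargetRegion

CHROM = {"BRCA1": "chr17", "BRCA2": "chr13"}


def make_panel(entries):
    """Build a small panel from (gene, exons, pool) tuples, in order.

    ``exons`` may be a string (single exon) or a tuple.  Regions get
    increasing coordinates per gene so panel order equals listing order
    (BRCA1 entries before BRCA2 as in any real panel file).
    """
    regions = []
    offset = {}
    for k, entry in enumerate(entries):
        gene, exons, pool = entry
        if isinstance(exons, str):
            exons = (exons,)
        start = 1_000_000 + offset.get(gene, 0)
        offset[gene] = offset.get(gene, 0) + 200
        regions.append(
            TargetRegion(
                chrom=CHROM[gene],
                start=start,
                end=start + 150,
                gene=gene,
                exons=tuple(exons),
                pool_id=pool,
                name=f"{gene}|{'-'.join(exons)}|r{k}",
            )
        )
    return Panel(regions)


def make_table(panel, depth, samples=None, clusters=None):
    depth = np.asarray(depth, dtype=float)
    if samples is None:
        samples = [f"S{j + 1}" for j in range(depth.shape[1])]
    return CoverageTable(
        panel=panel, samples=list(samples), depth=depth, cluster_of=clusters
    )


@pytest.fixture
def flat_panel():
    """Four single-region BRCA1 exons, no pools."""
    return make_panel(
        [("BRCA1", f"ex{i}", None) for i in (3, 4, 5, 6)]
    )


@pytest.fixture
def two_gene_panel():
    """Six BRCA1 + four BRCA2 single-exon regions, no pools."""
    entries = [("BRCA1", f"ex{i}", None) for i in range(3, 9)]
    entries += [("BRCA2", f"ex{i}", None) for i in range(10, 14)]
    return make_panel(entries)
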