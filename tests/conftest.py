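import textwrap

import pytest

from fruseq import gene_models as gm


@pytest.fixture
def toy_gff3() -> str:
    """One 2-isoform gene with shared, boundary-shifted and skipped exons,
    plus a second gene overlapping the first gene's last exon."""
    return textwrap.dedent(
        """\
        ##gff-version 3
        2L\ttest\tgene\t101\t1000\t.\t+\t.\tID=gA;Name=alpha
        2L\ttest\tmRNA\t101\t1000\t.\t+\t.\tID=gA.1;Parent=gA
        2L\ttest\texon\t101\t200\t.\t+\t.\tID=gA.1.e1;Parent=gA.1
        2L\ttest\texon\t301\t400\t.\t+\t.\tID=gA.1.e2;Parent=gA.1
        2L\ttest\texon\t801\t1000\t.\t+\t.\tID=gA.1.e3;Parent=gA.1
        2L\ttest\tmRNA\t101\t1000\t.\t+\t.\tID=gA.2;Parent=gA
        2L\ttest\texon\t101\t200\t.\t+\t.\tID=gA.2.e1;Parent=gA.2
        2L\ttest\texon\t301\t450\t.\t+\t.\tID=gA.2.e2;Parent=gA.2
        2L\ttest\tgene\t901\t1300\t.\t-\t.\tID=gB
        2L\ttest\tmRNA\t901\t1300\t.\t-\t.\tID=gB.1;Parent=gB
        2L\ttest\texon\t901\t1300\t.\t-\t.\tID=gB.1.e1;Parent=gB.1
        """
    )


@pytest.fixture
def toy_genes(toy_gff3):
    return gm.read_gene_models(toy_gff3)


def brute_force_regions(genes):
    """In-test interval-union oracle: iterate pairwise merges to fixpoint."""
    comps = [
        {"chrom": g.chrom, "start": s, "end": e,
         "members": {(g.gene_id, iso.isoform_id, s, e)}}
        for g in genes
        for iso in g.isoforms
        for s, e in iso.exons
    ]
    merged = True
    while merged:
        merged = False
        out = []
        while comps:
            cur = comps.pop()
            for other in comps:
                if (
                    cur["chrom"] == other["chrom"]
                    and cur["start"] < other["end"]
                    and other["start"] < cur["end"]
                ):
                    other["start"] = min(cur["start"], other["start"])
                    other["end"] = max(cur["end"], other["end"])
                    other["members"] |= cur["members"]
                    merged = True
                    break
            else:
                out.append(cur)
        comps = out
    return sorted(
        (c["chrom"], c["start"], c["end"], frozenset(c["members"])) for c in comps
    )
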