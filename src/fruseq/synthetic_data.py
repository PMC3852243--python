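"""Synthetic inputs with ground truth for every pipeline stage.

The generators emulate the statistical structure the analysis assumes —
multi-isoform gene models with overlapping and alternative exons, a
three-replicate (genotype x sex) count design with planted >= 2-fold
induced/repressed genes and between-strain background noise, SELEX clone
inserts with a planted binding word, and a genome with binding sites planted
preferentially in chosen genes — and return a truth record alongside each
artifact so recovery can be checked exactly. Every draw is reproducible
from the seed.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .gene_models import (
    ARM_NAMES,
    CLASS_ALTERNATIVE,
    CLASS_COMMON,
    CLASS_CONSTITUTIVE,
    CLASS_UNCLASSIFIED,
    GeneModel,
    Isoform,
)
from .quantification import (
    ExpressionMatrix,
    GENOTYPES,
    NULL_GENOTYPES,
    OVEREXPRESSION_GENOTYPES,
    SampleMeta,
)
from .selex_motif import CloneSet, revcomp
from .motif_scan import DEFAULT_FLANK

import pandas as pd

BASES = "ACGT"

#: Constant flanks of the SELEX selection oligo (25 nt each side of the
#: 26-nt random insert).
OLIGO_R76_FLANK_LEFT = "CAGGTCAGTTCAGCGGATCCTGTCG"
OLIGO_R76_FLANK_RIGHT = "GAGGCGAATTCAGTGCAACTGCAGC"

#: Consensus binding words of the three Fru DNA-binding domains.
FRU_CONSENSUS = {"FruA": "AGTAAC", "FruB": "GCCCTTT", "FruC": "TGTTACATCA"}


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Gene models
# ---------------------------------------------------------------------------

def _merge_oracle(
    exons: Sequence[tuple[str, int, int, str, str]],
) -> list[dict]:
    """Brute-force interval-union oracle: all pairwise overlap edges + DSU.

    Deliberately independent of the sorted sweep used by the flattening
    module: every same-chromosome exon pair is tested for overlap and the
    connected components are taken with union-find.
    """
    parent = list(range(len(exons)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    by_chrom: dict[str, list[int]] = {}
    for idx, (c, *_rest) in enumerate(exons):
        by_chrom.setdefault(c, []).append(idx)
    for idxs in by_chrom.values():
        for ii in range(len(idxs)):
            _, s1, e1, _, _ = exons[idxs[ii]]
            for jj in range(ii + 1, len(idxs)):
                _, s2, e2, _, _ = exons[idxs[jj]]
                if s1 < e2 and s2 < e1:
                    ri, rj = find(idxs[ii]), find(idxs[jj])
                    if ri != rj:
                        parent[ri] = rj

    groups: dict[int, list[int]] = {}
    for idx in range(len(exons)):
        groups.setdefault(find(idx), []).append(idx)
    comps = []
    for members_idx in groups.values():
        members = [
            (exons[i][3], exons[i][4], exons[i][1], exons[i][2])
            for i in members_idx
        ]
        comps.append(
            {
                "chrom": exons[members_idx[0]][0],
                "start": min(exons[i][1] for i in members_idx),
                "end": max(exons[i][2] for i in members_idx),
                "members": members,
            }
        )
    comps.sort(key=lambda c: (c["chrom"], c["start"]))
    return comps


def _classify_oracle(members, genes_by_id) -> str:
    gene_ids = {g for g, _, _, _ in members}
    if len(gene_ids) > 1:
        return CLASS_UNCLASSIFIED
    gene = genes_by_id[next(iter(gene_ids))]
    isoform_ids = {iso.isoform_id for iso in gene.isoforms}
    contributing = {i for _, i, _, _ in members}
    intervals = {(s, e) for _, _, s, e in members}
    if len(intervals) == 1 and contributing == isoform_ids:
        return CLASS_CONSTITUTIVE
    if contributing == isoform_ids:
        return CLASS_COMMON
    return CLASS_ALTERNATIVE


def generate_gene_models(
    n_genes: int = 200,
    isoforms_per_gene: tuple[int, int] = (1, 3),
    exons_per_isoform: tuple[int, int] = (2, 5),
    p_cross_gene_overlap: float = 0.05,
    p_skip_exon: float = 0.3,
    p_alt_boundary: float = 0.5,
    exon_len: tuple[int, int] = (80, 300),
    intron_len: tuple[int, int] = (80, 400),
    gene_spacing: tuple[int, int] = (300, 1500),
    arms: Sequence[str] = ARM_NAMES,
    seed=None,
) -> tuple[list[GeneModel], str, dict]:
    """Generate gene models with alternative structures and a truth record.

    Returns (gene models, GFF3 text, truth). The truth's expected regions
    are computed with an O(n^2) pairwise merge oracle coded independently of
    the production flattening sweep.
    """
    if n_genes < 1 or isoforms_per_gene[0] < 1 or exons_per_isoform[0] < 1:
        raise ValueError("infeasible generator parameters")
    rng = _rng(seed)
    cursors = {arm: int(rng.integers(1000, 3000)) for arm in arms}
    genes: list[GeneModel] = []
    prev_on_arm: dict[str, GeneModel] = {}

    for gi in range(n_genes):
        arm = arms[gi % len(arms)]
        n_exons = int(rng.integers(exons_per_isoform[0], exons_per_isoform[1] + 1))
        start = cursors[arm]
        cross = (
            arm in prev_on_arm
            and p_cross_gene_overlap > 0
            and rng.random() < p_cross_gene_overlap
        )
        if cross:
            prev_end = prev_on_arm[arm].span[1]
            start = max(0, prev_end - int(rng.integers(20, 61)))

        # master exon chain
        chain = []
        pos = start
        for _ in range(n_exons):
            length = int(rng.integers(exon_len[0], exon_len[1] + 1))
            chain.append((pos, pos + length))
            pos += length + int(rng.integers(intron_len[0], intron_len[1] + 1))

        n_iso = int(rng.integers(isoforms_per_gene[0], isoforms_per_gene[1] + 1))
        gene_id = f"FBgn{gi + 1:07d}"
        isoforms = [Isoform(f"{gene_id}.1", tuple(chain))]
        for k in range(2, n_iso + 1):
            keep = [e for e in chain if rng.random() >= p_skip_exon]
            if not keep:
                keep = [chain[int(rng.integers(len(chain)))]]
            keep = sorted(keep)
            if rng.random() < p_alt_boundary:
                s, e = keep[0]
                shift = int(rng.integers(1, max(2, (e - s) // 2)))
                keep[0] = (s + shift, e) if rng.random() < 0.5 else (max(0, s - shift), e)
            if rng.random() < p_alt_boundary:
                s, e = keep[-1]
                shift = int(rng.integers(1, max(2, (e - s) // 2)))
                keep[-1] = (s, e - shift) if rng.random() < 0.5 else (s, e + shift)
            keep = sorted(set(keep))
            # drop boundary tweaks that made exons collide
            ok, last_end = [], -1
            for s, e in keep:
                if s >= last_end and e > s:
                    ok.append((s, e))
                    last_end = e
            isoforms.append(Isoform(f"{gene_id}.{k}", tuple(ok)))
        gene = GeneModel(
            gene_id=gene_id,
            chrom=arm,
            strand="+" if rng.random() < 0.5 else "-",
            isoforms=tuple(isoforms),
        )
        genes.append(gene)
        prev_on_arm[arm] = gene
        cursors[arm] = gene.span[1] + int(
            rng.integers(gene_spacing[0], gene_spacing[1] + 1)
        )

    gff3 = genes_to_gff3(genes)

    genes_by_id = {g.gene_id: g for g in genes}
    exon_records = [
        (g.chrom, s, e, g.gene_id, iso.isoform_id)
        for g in genes
        for iso in g.isoforms
        for s, e in iso.exons
    ]
    comps = _merge_oracle(exon_records)
    expected_regions = []
    n_single = n_alt = n_cross = 0
    for c in comps:
        n_distinct = len({(s, e) for _, _, s, e in c["members"]})
        n_genes_in = len({g for g, _, _, _ in c["members"]})
        if n_distinct == 1:
            n_single += 1
        elif n_genes_in > 1:
            n_cross += 1
        else:
            n_alt += 1
        expected_regions.append(
            {
                "chrom": c["chrom"],
                "start": c["start"],
                "end": c["end"],
                "n_source_exons": n_distinct,
                "cross_gene": n_genes_in > 1,
                "classification": _classify_oracle(c["members"], genes_by_id),
            }
        )
    truth = {
        "seed": None if isinstance(seed, np.random.Generator) else seed,
        "n_genes": n_genes,
        "expected_regions": expected_regions,
        "expected_counts": {
            "total": len(comps),
            "singleton": n_single,
            "alt_start_end": n_alt,
            "cross_gene": n_cross,
        },
    }
    return genes, gff3, truth


def genes_to_gff3(genes: Iterable[GeneModel]) -> str:
    lines = ["##gff-version 3"]
    for g in genes:
        s, e = g.span
        lines.append(
            f"{g.chrom}\tfruseq\tgene\t{s + 1}\t{e}\t.\t{g.strand}\t.\tID={g.gene_id}"
        )
        for iso in g.isoforms:
            is_, ie = iso.exons[0][0], iso.exons[-1][1]
            lines.append(
                f"{g.chrom}\tfruseq\tmRNA\t{is_ + 1}\t{ie}\t.\t{g.strand}\t.\t"
                f"ID={iso.isoform_id};Parent={g.gene_id}"
            )
            for j, (xs, xe) in enumerate(iso.exons, 1):
                lines.append(
                    f"{g.chrom}\tfruseq\texon\t{xs + 1}\t{xe}\t.\t{g.strand}\t.\t"
                    f"ID={iso.isoform_id}.e{j};Parent={iso.isoform_id}"
                )
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Count design
# ---------------------------------------------------------------------------

def default_design(
    n_replicates: int = 3,
    depth: int = 2_000_000,
    genotypes: Sequence[str] = GENOTYPES,
) -> list[SampleMeta]:
    """The study design: 3 replicates of each (genotype, sex) cell.

    Wild types and over-expressors exist in both sexes; the two fru P1 null
    allele combinations only in males.
    """
    samples = []
    for g in genotypes:
        sexes = ("male",) if g in NULL_GENOTYPES else ("male", "female")
        for sex in sexes:
            for rep in range(1, n_replicates + 1):
                samples.append(
                    SampleMeta(
                        sample_id=f"{g}_{sex}_{rep}",
                        genotype=g,
                        sex=sex,
                        replicate=rep,
                        total_mapped_reads=depth,
                    )
                )
    return samples


def generate_counts(
    region_ids: Sequence[str],
    lengths: Sequence[int],
    region_to_gene: Mapping[str, str],
    samples: Sequence[SampleMeta],
    planted_folds: Mapping[tuple[str, str], Mapping[str, float]] | None = None,
    baseline_lnrpkm_mean: float = 2.5,
    baseline_lnrpkm_sd: float = 1.0,
    strain_sd: float = 0.1,
    dispersion: float = 0.1,
    seed=None,
) -> tuple[ExpressionMatrix, dict]:
    """Simulate the region x sample count matrix.

    ``planted_folds`` maps a (genotype, sex) condition to {gene_id: fold};
    every region of a planted gene has its mean multiplied by the fold in
    that condition's samples (fold > 1 induced, < 1 repressed; must be > 0).
    Each genotype carries an independent per-region lognormal background
    factor of scale ``strain_sd`` (strain noise). Counts are negative
    binomial around mean = RPKM * length/1e3 * depth/1e6 with variance
    mu + dispersion * mu^2; ``dispersion=0`` yields the deterministic means,
    rounded.
    """
    rng = _rng(seed)
    planted_folds = planted_folds or {}
    for cond, folds in planted_folds.items():
        if any(f <= 0 for f in folds.values()):
            raise ValueError("planted fold must be > 0")

    region_ids = list(region_ids)
    lengths_arr = np.asarray(lengths, dtype=float)
    n_regions = len(region_ids)
    baseline = rng.normal(baseline_lnrpkm_mean, baseline_lnrpkm_sd, size=n_regions)
    genotypes = sorted({s.genotype for s in samples})
    strain_factor = {
        g: rng.normal(0.0, strain_sd, size=n_regions) if strain_sd > 0 else np.zeros(n_regions)
        for g in genotypes
    }

    gene_idx: dict[str, list[int]] = {}
    for i, rid in enumerate(region_ids):
        gene = region_to_gene.get(rid)
        if gene is not None:
            gene_idx.setdefault(gene, []).append(i)

    counts = np.zeros((n_regions, len(samples)), dtype=np.int64)
    for j, s in enumerate(samples):
        ln_mu = baseline + strain_factor[s.genotype]
        folds = planted_folds.get((s.genotype, s.sex), {})
        ln_fold = np.zeros(n_regions)
        for gene, fold in folds.items():
            for i in gene_idx.get(gene, []):
                ln_fold[i] = np.log(fold)
        depth = s.total_mapped_reads or 2_000_000
        mu = np.exp(ln_mu + ln_fold) * lengths_arr / 1e3 * depth / 1e6
        if dispersion > 0:
            size = 1.0 / dispersion
            p = size / (size + mu)
            counts[:, j] = rng.negative_binomial(size, p)
        else:
            counts[:, j] = np.rint(mu).astype(np.int64)

    matrix = ExpressionMatrix(
        counts=pd.DataFrame(
            counts, index=region_ids, columns=[s.sample_id for s in samples]
        ),
        lengths=pd.Series(lengths_arr, index=region_ids, name="length"),
        samples=list(samples),
    )
    truth = {
        "planted_folds": {
            f"{g}:{sex}": dict(folds) for (g, sex), folds in planted_folds.items()
        },
        "baseline_lnrpkm_mean": baseline_lnrpkm_mean,
        "baseline_lnrpkm_sd": baseline_lnrpkm_sd,
        "strain_sd": strain_sd,
        "dispersion": dispersion,
    }
    return matrix, truth


# ---------------------------------------------------------------------------
# SELEX clones
# ---------------------------------------------------------------------------

def generate_selex_clones(
    word: str,
    n_clones: int = 20,
    insert_len: int = 26,
    mutation_rate: float = 0.0,
    flank_left: str = "",
    flank_right: str = "",
    strand: str = "plus",
    seed=None,
) -> tuple[CloneSet, dict]:
    """Clone inserts each carrying the planted word at a random offset.

    The planted word's bases are mutated independently at ``mutation_rate``.
    ``strand='plus'`` plants the word in insert orientation (clone inserts
    are directionally ligated); ``strand='both'`` plants the reverse
    complement half the time.
    """
    word = word.upper()
    if len(word) > insert_len:
        raise ValueError("word longer than insert")
    if strand not in ("plus", "both"):
        raise ValueError("strand must be 'plus' or 'both'")
    rng = _rng(seed)
    seqs, offsets, strands = [], [], []
    for _ in range(n_clones):
        insert = list(rng.choice(list(BASES), size=insert_len))
        offset = int(rng.integers(0, insert_len - len(word) + 1))
        minus = strand == "both" and rng.random() < 0.5
        planted = revcomp(word) if minus else word
        for k, base in enumerate(planted):
            if mutation_rate > 0 and rng.random() < mutation_rate:
                base = rng.choice([b for b in BASES if b != base])
            insert[offset + k] = base
        seqs.append(flank_left.upper() + "".join(insert) + flank_right.upper())
        offsets.append(offset)
        strands.append("-" if minus else "+")
    clones = CloneSet(sequences=tuple(seqs), label=f"planted:{word}")
    truth = {
        "word": word,
        "offsets": offsets,
        "strands": strands,
        "mutation_rate": mutation_rate,
        "insert_len": insert_len,
        "flank_left": flank_left,
        "flank_right": flank_right,
    }
    return clones, truth


def clones_to_fasta(clones: CloneSet) -> str:
    return "".join(
        f">clone_{i + 1}\n{s}\n" for i, s in enumerate(clones.sequences)
    )


# ---------------------------------------------------------------------------
# Genome with planted sites
# ---------------------------------------------------------------------------

def _find_word(chrom_arr: np.ndarray, word_arr: np.ndarray) -> np.ndarray:
    if len(chrom_arr) < len(word_arr):
        return np.array([], dtype=int)
    win = np.lib.stride_tricks.sliding_window_view(chrom_arr, len(word_arr))
    return np.flatnonzero((win == word_arr).all(axis=1))


def generate_genome_with_sites(
    genes: Sequence[GeneModel],
    motifs: Mapping[str, str],
    positive_genes: Mapping[str, set] | None = None,
    p_positive: Mapping[str, float] | float = 0.3,
    induced_genes: set | None = None,
    p_induced: float | None = None,
    sites_per_positive: tuple[int, int] = (1, 3),
    gc_content: float = 0.42,
    flank: int = DEFAULT_FLANK,
    seed=None,
) -> tuple[dict[str, str], dict]:
    """Random genome with exact consensus words planted in gene scan regions.

    Site-positive genes are either given per motif (``positive_genes``) or
    drawn per gene with probability ``p_positive`` — raised to ``p_induced``
    for genes in ``induced_genes``, which links binding sites to the planted
    induced set. The background is scrubbed of accidental exact matches to
    any motif (both strands), so the scanner's exact-word hit table equals
    the planting truth. The truth's per-gene site counts are evaluated
    against every gene's scan region, so sites in overlapping flanks are
    attributed to all genes that would see them.
    """
    rng = _rng(seed)
    base_p = np.array(
        [(1 - gc_content) / 2, gc_content / 2, gc_content / 2, (1 - gc_content) / 2]
    )
    word_ints = {
        m: np.fromiter((BASES.index(b) for b in w.upper()), dtype=np.int64)
        for m, w in motifs.items()
    }
    rc_ints = {
        m: np.fromiter((BASES.index(b) for b in revcomp(w)), dtype=np.int64)
        for m, w in motifs.items()
    }

    chrom_lengths: dict[str, int] = {}
    for g in genes:
        chrom_lengths[g.chrom] = max(
            chrom_lengths.get(g.chrom, 0), g.span[1] + flank + 100
        )
    chrom_arrays = {
        c: rng.choice(4, size=n, p=base_p) for c, n in chrom_lengths.items()
    }

    # choose positive genes and plant positions
    planted: dict[str, list[dict]] = {m: [] for m in motifs}
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_lengths}
    max_w = max(len(w) for w in motifs.values())
    for g in genes:
        s, e = g.span
        lo, hi = max(0, s - flank), min(chrom_lengths[g.chrom], e + flank)
        for m, w in motifs.items():
            if positive_genes is not None:
                positive = g.gene_id in positive_genes.get(m, set())
            else:
                p = p_positive[m] if isinstance(p_positive, Mapping) else p_positive
                if (
                    induced_genes is not None
                    and p_induced is not None
                    and g.gene_id in induced_genes
                ):
                    p = p_induced
                positive = rng.random() < p
            if not positive:
                continue
            k = int(rng.integers(sites_per_positive[0], sites_per_positive[1] + 1))
            for _ in range(k):
                for _attempt in range(200):
                    pos = int(rng.integers(lo, hi - len(w)))
                    window = (pos - max_w, pos + len(w) + max_w)
                    if all(
                        window[1] <= os or window[0] >= oe
                        for os, oe in occupied[g.chrom]
                    ):
                        break
                else:
                    raise ValueError(
                        f"could not place a site for {g.gene_id} without collision"
                    )
                minus = rng.random() < 0.5
                ints = rc_ints[m] if minus else word_ints[m]
                chrom_arrays[g.chrom][pos : pos + len(w)] = ints
                occupied[g.chrom].append((pos, pos + len(w)))
                planted[m].append(
                    {
                        "chrom": g.chrom,
                        "pos": pos,
                        "strand": "-" if minus else "+",
                        "gene_id": g.gene_id,
                    }
                )

    # scrub accidental matches (both strands) outside planted windows
    planted_windows = {
        c: sorted(
            (p["pos"], p["pos"] + len(motifs[m]))
            for m in motifs
            for p in planted[m]
            if p["chrom"] == c
        )
        for c in chrom_lengths
    }
    for _pass in range(20):
        dirty = False
        for c, arr in chrom_arrays.items():
            wins = planted_windows[c]
            for m in motifs:
                w = len(motifs[m])
                for target in (word_ints[m], rc_ints[m]):
                    for pos in _find_word(arr, target):
                        pos = int(pos)
                        if any(pos >= ws and pos + w <= we for ws, we in wins):
                            continue  # a planted site
                        # mutate a base of this window outside planted windows
                        for off in range(w // 2, -1, -1) if w else []:
                            b = pos + off
                            if not any(ws <= b < we for ws, we in wins):
                                choices = [x for x in range(4) if x != arr[b]]
                                arr[b] = rng.choice(choices)
                                dirty = True
                                break
                        else:
                            raise ValueError("accidental match inside planted sites")
        if not dirty:
            break
    else:
        raise ValueError("could not scrub accidental motif matches")

    genome = {c: "".join(BASES[i] for i in arr) for c, arr in chrom_arrays.items()}

    # per-gene truth over scan regions
    site_counts: dict[str, dict[str, int]] = {
        g.gene_id: {m: 0 for m in motifs} for g in genes
    }
    for g in genes:
        s, e = g.span
        lo, hi = max(0, s - flank), min(chrom_lengths[g.chrom], e + flank)
        for m, w in motifs.items():
            for p in planted[m]:
                if p["chrom"] == g.chrom and lo <= p["pos"] and p["pos"] + len(w) <= hi:
                    site_counts[g.gene_id][m] += 1
    truth = {
        "planted_sites": planted,
        "site_counts": site_counts,
        "chrom_lengths": chrom_lengths,
        "gc_content": gc_content,
        "flank": flank,
    }
    return genome, truth


def genome_to_fasta(genome: Mapping[str, str], width: int = 80) -> str:
    parts = []
    for chrom in sorted(genome):
        parts.append(f">{chrom}\n")
        seq = genome[chrom]
        for i in range(0, len(seq), width):
            parts.append(seq[i : i + width] + "\n")
    return "".join(parts)


# ---------------------------------------------------------------------------
# Full bundle
# ---------------------------------------------------------------------------

def simulate_all(seed: int, outdir: str | Path | None = None) -> dict:
    """Generate a coherent full-pipeline input bundle from one master seed.

    Returns a dict with the in-memory artifacts and the combined truth; when
    ``outdir`` is given the standard files (annotation.gff3, counts.tsv,
    samples.tsv, genome.fa, clones_<isoform>.fa, gene_arms.tsv, truth.json)
    are written there.
    """
    from .gene_models import build_exonic_regions, region_to_gene_map
    from .quantification import compute_lnrpkm, write_counts

    rng = np.random.default_rng(seed)
    # wide spacing keeps neighbouring scan regions (span +/- 2 kb) mostly
    # disjoint, as in the fly genome
    genes, gff3, gm_truth = generate_gene_models(
        n_genes=120, gene_spacing=(4500, 8000), seed=int(rng.integers(2**31))
    )
    regions, summary = build_exonic_regions(genes)
    usable = [r for r in regions if not r.cross_gene]
    r2g = region_to_gene_map(usable)

    gene_ids = [g.gene_id for g in genes]
    pick = rng.permutation(len(gene_ids))
    induced = {gene_ids[i] for i in pick[:15]}
    repressed = {gene_ids[i] for i in pick[15:23]}
    planted_folds = {}
    for g in OVEREXPRESSION_GENOTYPES:
        planted_folds[(g, "male")] = {
            **{x: 4.0 for x in induced},
            **{x: 0.25 for x in repressed},
        }
    for g in NULL_GENOTYPES:
        planted_folds[(g, "male")] = {x: 0.4 for x in induced}

    samples = default_design()
    matrix, counts_truth = generate_counts(
        [r.region_id for r in usable],
        [r.length for r in usable],
        r2g,
        samples,
        planted_folds=planted_folds,
        seed=int(rng.integers(2**31)),
    )
    matrix = compute_lnrpkm(matrix)

    clones = {}
    clone_truth = {}
    for name, word in FRU_CONSENSUS.items():
        clones[name], clone_truth[name] = generate_selex_clones(
            word, n_clones=20, mutation_rate=0.03, seed=int(rng.integers(2**31))
        )

    genome, genome_truth = generate_genome_with_sites(
        genes,
        FRU_CONSENSUS,
        induced_genes=induced,
        p_induced=0.9,
        p_positive=0.15,
        seed=int(rng.integers(2**31)),
    )

    truth = {
        "seed": seed,
        "gene_models": gm_truth["expected_counts"],
        "planted_induced": sorted(induced),
        "planted_repressed": sorted(repressed),
        "counts": counts_truth,
        "clones": clone_truth,
        "genome": {k: genome_truth[k] for k in ("site_counts", "flank", "gc_content")},
    }
    bundle = {
        "genes": genes,
        "gff3": gff3,
        "regions": regions,
        "summary": summary,
        "matrix": matrix,
        "clones": clones,
        "genome": genome,
        "truth": truth,
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "annotation.gff3").write_text(gff3)
        write_counts(matrix, outdir / "counts.tsv")
        with open(outdir / "samples.tsv", "w") as fh:
            fh.write("sample_id\tgenotype\tsex\treplicate\ttotal_mapped_reads\n")
            for s in samples:
                fh.write(
                    f"{s.sample_id}\t{s.genotype}\t{s.sex}\t{s.replicate}\t"
                    f"{s.total_mapped_reads}\n"
                )
        (outdir / "genome.fa").write_text(genome_to_fasta(genome))
        for name, cs in clones.items():
            (outdir / f"clones_{name}.fa").write_text(clones_to_fasta(cs))
        with open(outdir / "gene_arms.tsv", "w") as fh:
            fh.write("gene_id\tarm\n")
            for g in genes:
                fh.write(f"{g.gene_id}\t{g.arm}\n")
        (outdir / "truth.json").write_text(json.dumps(truth, indent=1, default=str))
    return bundle
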