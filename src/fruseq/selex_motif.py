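"""Motif discovery from SELEX clone inserts via a Gibbs site sampler.

After several rounds of in vitro selection, each sequenced clone insert is
assumed to carry exactly one binding site for the selected DNA-binding
domain (one-occurrence-per-sequence model: the random inserts are short and
each clone is one selected binder). The sampler infers the common site:

1. initialise one site (position, strand) per sequence uniformly at random;
2. repeatedly withhold one sequence, build the count matrix / PWM from the
   remaining sites (with pseudocounts) and the background from the remaining
   sequences' non-site positions, then resample the withheld sequence's site
   with probability proportional to the PWM/background likelihood ratio;
3. keep the best configuration seen, scored by the information content of
   the site alignment, across several random restarts.

Both strands are considered: a site may be the reverse complement of the
window it occupies. Runs are deterministic given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


def seq_to_ints(seq: str) -> np.ndarray:
    try:
        return np.fromiter((_BASE_INDEX[b] for b in seq.upper()), dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"non-ACGT base in sequence: {exc}") from exc


def ints_to_seq(arr: np.ndarray) -> str:
    return "".join(BASES[i] for i in arr)


def revcomp(seq: str) -> str:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    return "".join(comp[b] for b in reversed(seq.upper()))


@dataclass(frozen=True)
class CloneSet:
    """Sequenced SELEX clone inserts for one DNA-binding domain."""

    sequences: tuple[str, ...]
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequences", tuple(s.upper() for s in self.sequences))
        if len(self.sequences) < 2:
            raise ValueError("a clone set needs at least 2 sequences")


@dataclass
class MotifModel:
    """A gapless motif: aligned sites, count matrix, PWM, log-odds, consensus."""

    width: int
    count_matrix: np.ndarray        # 4 x W, integer counts (no pseudocounts)
    pwm: np.ndarray                 # 4 x W, columns sum to 1
    log_odds: np.ndarray            # 4 x W, ln(pwm / background)
    consensus: str
    information_content: float      # bits, summed over columns
    background: np.ndarray          # length-4 base frequencies
    site_assignments: tuple[tuple[int, int], ...] | None = None  # (pos, strand)

    @property
    def max_score(self) -> float:
        """Highest achievable log-odds score of any word."""
        return float(self.log_odds.max(axis=0).sum())


def _information_content(pwm: np.ndarray) -> float:
    with np.errstate(divide="ignore", invalid="ignore"):
        h = np.where(pwm > 0, pwm * np.log2(pwm), 0.0).sum(axis=0)
    return float((2.0 + h).sum())


def build_pwm(
    sites: Sequence[str],
    pseudocount: float = 0.25,
    background: Sequence[float] | None = None,
) -> MotifModel:
    """Build count matrix, PWM, log-odds and consensus from aligned sites.

    Consensus ties break alphabetically (A < C < G < T). The background
    defaults to uniform.
    """
    if not sites:
        raise ValueError("empty site list")
    width = len(sites[0])
    if any(len(s) != width for s in sites):
        raise ValueError("sites must share one width")
    counts = np.zeros((4, width), dtype=np.int64)
    for s in sites:
        ints = seq_to_ints(s)
        counts[ints, np.arange(width)] += 1
    bg = (
        np.full(4, 0.25)
        if background is None
        else np.asarray(background, dtype=float) / np.sum(background)
    )
    pwm = (counts + pseudocount) / (len(sites) + 4.0 * pseudocount)
    with np.errstate(divide="ignore"):
        log_odds = np.log(pwm / bg[:, None])
    consensus = ints_to_seq(pwm.argmax(axis=0))
    return MotifModel(
        width=width,
        count_matrix=counts,
        pwm=pwm,
        log_odds=log_odds,
        consensus=consensus,
        information_content=_information_content(pwm),
        background=bg,
    )


def consensus_motif(word: str, pseudocount: float = 0.0) -> MotifModel:
    """A degenerate single-word motif, handy for exact-word scanning."""
    return build_pwm([word], pseudocount=pseudocount)


# ---------------------------------------------------------------------------
# Gibbs site sampler
# ---------------------------------------------------------------------------

def _site_word(seq: np.ndarray, pos: int, strand: int, width: int) -> np.ndarray:
    w = seq[pos : pos + width]
    return w if strand > 0 else 3 - w[::-1]


def gibbs_motif_search(
    clones: CloneSet | Sequence[str],
    width: int,
    n_restarts: int = 3,
    n_iterations: int = 100,
    pseudocount: float = 0.25,
    seed: int | None = None,
    both_strands: bool = True,
    plateau: int = 30,
) -> MotifModel:
    """Find the common motif of width ``width`` in a set of clone inserts.

    ``plateau`` stops a restart early when the best information content has
    not improved for that many sweeps. Returns the motif rebuilt from the
    best site configuration, with the background estimated from the clones'
    non-site positions.
    """
    seqs = clones.sequences if isinstance(clones, CloneSet) else tuple(clones)
    arrs = [seq_to_ints(s) for s in seqs]
    n = len(arrs)
    if n < 2:
        raise ValueError("need at least 2 sequences")
    if any(len(a) < width for a in arrs):
        raise ValueError("motif width exceeds a sequence length")
    rng = np.random.default_rng(seed)
    strands = (1, -1) if both_strands else (1,)

    # per-sequence candidate word matrices, one row per (pos, strand)
    cand_words: list[np.ndarray] = []
    cand_sites: list[list[tuple[int, int]]] = []
    for a in arrs:
        n_pos = len(a) - width + 1
        win = np.lib.stride_tricks.sliding_window_view(a, width)
        words = [win]
        sites = [(p, 1) for p in range(n_pos)]
        if both_strands:
            words.append(3 - win[:, ::-1])
            sites += [(p, -1) for p in range(n_pos)]
        cand_words.append(np.concatenate(words, axis=0))
        cand_sites.append(sites)

    total_base_counts = np.zeros(4, dtype=np.int64)
    for a in arrs:
        total_base_counts += np.bincount(a, minlength=4)
    cols = np.arange(width)

    best_ic = -np.inf
    best_assign: list[tuple[int, int]] | None = None

    for _ in range(n_restarts):
        assign = [
            cand_sites[i][rng.integers(len(cand_sites[i]))] for i in range(n)
        ]
        counts = np.zeros((4, width), dtype=np.int64)
        site_base = np.zeros(4, dtype=np.int64)
        for i in range(n):
            w = _site_word(arrs[i], assign[i][0], assign[i][1], width)
            counts[w, cols] += 1
            site_base += np.bincount(arrs[i][assign[i][0] : assign[i][0] + width], minlength=4)

        since_improved = 0
        for _ in range(n_iterations):
            for z in rng.permutation(n):
                w = _site_word(arrs[z], assign[z][0], assign[z][1], width)
                counts[w, cols] -= 1
                site_base -= np.bincount(
                    arrs[z][assign[z][0] : assign[z][0] + width], minlength=4
                )
                q = (counts + pseudocount) / (n - 1 + 4.0 * pseudocount)
                bg_counts = (
                    total_base_counts
                    - np.bincount(arrs[z], minlength=4)
                    - site_base
                )
                bg = (bg_counts + 1.0) / (bg_counts.sum() + 4.0)
                logratio = np.log(q) - np.log(bg)[:, None]
                scores = logratio[cand_words[z], cols].sum(axis=1)
                p = np.exp(scores - scores.max())
                p /= p.sum()
                k = rng.choice(len(p), p=p)
                assign[z] = cand_sites[z][k]
                w = cand_words[z][k]
                counts[w, cols] += 1
                site_base += np.bincount(
                    arrs[z][assign[z][0] : assign[z][0] + width], minlength=4
                )
            # phase-shift move: sliding every site by the same offset escapes
            # the shifted local optima the plain sampler is prone to
            def _config_ic(a: list[tuple[int, int]]) -> float:
                cts = np.zeros((4, width), dtype=np.int64)
                for i2 in range(n):
                    w2 = _site_word(arrs[i2], a[i2][0], a[i2][1], width)
                    cts[w2, cols] += 1
                return _information_content(
                    (cts + pseudocount) / (n + 4.0 * pseudocount)
                )

            cur_ic = _config_ic(assign)
            best_shift, best_shift_ic = 0, cur_ic
            for delta in (-2, -1, 1, 2):
                if all(
                    0 <= p + delta <= len(arrs[i2]) - width
                    for i2, (p, _) in enumerate(assign)
                ):
                    ic_d = _config_ic([(p + delta, s) for p, s in assign])
                    if ic_d > best_shift_ic:
                        best_shift, best_shift_ic = delta, ic_d
            if best_shift != 0:
                assign = [(p + best_shift, s) for p, s in assign]
                counts = np.zeros((4, width), dtype=np.int64)
                site_base = np.zeros(4, dtype=np.int64)
                for i2 in range(n):
                    w2 = _site_word(arrs[i2], assign[i2][0], assign[i2][1], width)
                    counts[w2, cols] += 1
                    site_base += np.bincount(
                        arrs[i2][assign[i2][0] : assign[i2][0] + width], minlength=4
                    )
            ic = best_shift_ic
            if ic > best_ic:
                best_ic = ic
                best_assign = list(assign)
                since_improved = 0
            else:
                since_improved += 1
                if since_improved >= plateau:
                    break

    if best_assign is None:  # pragma: no cover - n_restarts >= 1 guarantees this
        raise RuntimeError("no configuration sampled")

    # canonical orientation: report the motif as read on the forward strand
    # by the majority of sites (ties keep the forward reading)
    n_minus = sum(1 for _, s in best_assign if s < 0)
    if n_minus > n - n_minus:
        best_assign = [(p, -s) for p, s in best_assign]
    site_words = [
        ints_to_seq(_site_word(arrs[i], best_assign[i][0], best_assign[i][1], width))
        for i in range(n)
    ]
    non_site = total_base_counts.astype(float).copy()
    for i in range(n):
        non_site -= np.bincount(
            arrs[i][best_assign[i][0] : best_assign[i][0] + width], minlength=4
        )
    if non_site.sum() <= 0:
        non_site = np.full(4, 1.0)
    model = build_pwm(site_words, pseudocount=pseudocount, background=non_site)
    model.site_assignments = tuple(best_assign)
    return model


# ---------------------------------------------------------------------------
# Reproducibility check
# ---------------------------------------------------------------------------

def consensus_agreement(
    m1: MotifModel | str, m2: MotifModel | str
) -> tuple[float, int, str]:
    """Best per-column match fraction between two consensus words.

    All offsets and both orientations of the second word are tried; the
    fraction is matches / max(width1, width2), so only a full-width,
    same-orientation (or reverse-complement) agreement scores 1.0. Returns
    (fraction, offset, strand) with strand '+' or '-'.
    """
    c1 = m1.consensus if isinstance(m1, MotifModel) else m1.upper()
    c2 = m2.consensus if isinstance(m2, MotifModel) else m2.upper()
    denom = max(len(c1), len(c2))
    best = (0.0, 0, "+")
    for strand, cand in (("+", c2), ("-", revcomp(c2))):
        for offset in range(-(len(cand) - 1), len(c1)):
            matches = sum(
                1
                for j in range(len(cand))
                if 0 <= offset + j < len(c1) and c1[offset + j] == cand[j]
            )
            frac = matches / denom
            if frac > best[0]:
                best = (frac, offset, strand)
    return best


def width_scan(
    clones: CloneSet | Sequence[str],
    widths: Iterable[int],
    seed: int | None = None,
    **kwargs,
) -> dict[int, MotifModel]:
    """Run the sampler over a range of widths.

    The information content per free parameter (IC / (3 * W)) of each model
    lets the caller pick a width when none is known a priori.
    """
    rng = np.random.default_rng(seed)
    return {
        w: gibbs_motif_search(clones, w, seed=int(rng.integers(2**31)), **kwargs)
        for w in widths
    }


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def read_clones_fasta(path: str | Path, label: str = "") -> CloneSet:
    seqs = tuple(str(rec.seq) for rec in SeqIO.parse(str(path), "fasta"))
    return CloneSet(sequences=seqs, label=label or Path(path).stem)


def trim_flanks(clones: CloneSet, left: str = "", right: str = "") -> CloneSet:
    """Remove constant primer/vector flanks (when present) from every clone."""
    out = []
    for s in clones.sequences:
        if left and s.startswith(left.upper()):
            s = s[len(left):]
        if right and s.endswith(right.upper()):
            s = s[: len(s) - len(right)]
        out.append(s)
    return CloneSet(sequences=tuple(out), label=clones.label)


def write_meme(
    motifs: dict[str, MotifModel], path: str | Path
) -> None:
    """Write motifs in MEME minimal format."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write("A 0.25 C 0.25 G 0.25 T 0.25\n\n")
        for name, m in motifs.items():
            nsites = int(m.count_matrix[:, 0].sum()) or 1
            fh.write(f"MOTIF {name} {m.consensus}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {m.width} "
                f"nsites= {nsites} E= 0\n"
            )
            for col in m.pwm.T:
                fh.write(" " + " ".join(f"{x:.6f}" for x in col) + "\n")
            fh.write("\n")


def write_count_matrix(model: MotifModel, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("base\t" + "\t".join(str(i + 1) for i in range(model.width)) + "\n")
        for b, row in zip(BASES, model.count_matrix):
            fh.write(b + "\t" + "\t".join(str(int(x)) for x in row) + "\n")
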