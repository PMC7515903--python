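"""Seed-and-extend reconstruction of repetitive silk genes (SMoC-style).

Spidroin genes defeat ordinary short-read assembly: a multi-kilobase tandem
array collapses in the de Bruijn graph, leaving contigs that carry the
non-repetitive terminal domains and at most a copy or two of the repeat.
The curation strategy implemented here recovers the missing structure:

1. terminal/repeat *seeds* are found on contigs by translated local
   alignment against known spidroin domain profiles;
2. short reads containing an exact, very large k-mer (default k=100 of
   150 bp reads) of the growing consensus 3' end are recruited, their
   3' overhangs stacked into a position weight matrix (PWM), and columns
   are accepted under stringent depth and purity thresholds;
3. extension stops when the consensus runs into the tandem array — either
   trailing periodicity is detected outright, or recruitment mixes nearly
   identical repeat copies and column purity collapses;
4. the repeat unit is read off the periodic region, and the copy number is
   estimated by tiling the unit along noisy long reads that span the whole
   gene, which also validates that NTD, repeats and CTD are one continuous
   molecule.

Coordinates are 0-based half-open; all matching is canonicalised over both
strands and reported on the seed's coding strand.
"""

from __future__ import annotations

import re
import warnings
from collections import Counter, defaultdict
from dataclasses import dataclass, field

import edlib
import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from ._seq import cyclic_identity, revcomp

_BASES = "ACGT"
_BASE_IDX = {b: i for i, b in enumerate(_BASES)}
_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


# ----------------------------------------------------------------------
# k-mer screening
# ----------------------------------------------------------------------
class KmerIndex:
    """Exact-match index of every k-mer of every read, on both strands.

    Values are ``(read_id, offset, strand)`` with the offset given on the
    oriented read (the read itself for '+', its reverse complement for '-'),
    so a lookup directly anchors the oriented read under the consensus.
    """

    def __init__(self, k: int):
        self.k = k
        self._map: dict[str, list[tuple[str, int, str]]] = defaultdict(list)

    def add(self, kmer: str, read_id: str, offset: int, strand: str) -> None:
        self._map[kmer].append((read_id, offset, strand))

    def lookup(self, kmer: str) -> list[tuple[str, int, str]]:
        return self._map.get(kmer, [])

    def __len__(self) -> int:
        return sum(len(v) for v in self._map.values())


def build_kmer_screen(reads: dict[str, str], k: int) -> KmerIndex:
    """Index all k-mers of ``reads`` (id -> sequence) on both strands."""
    if not reads:
        raise ValueError("no reads to index")
    min_len = min(len(s) for s in reads.values())
    if k > min_len:
        raise ValueError(f"k={k} exceeds shortest read length {min_len}")
    idx = KmerIndex(k)
    for rid, seq in reads.items():
        for strand, oriented in (("+", seq), ("-", revcomp(seq))):
            for off in range(len(oriented) - k + 1):
                idx.add(oriented[off : off + k], rid, off, strand)
    return idx


def recruit_and_align(
    kmer: str, index: KmerIndex, reads: dict[str, str]
) -> list[tuple[str, str]]:
    """Reads anchored by an exact k-mer match; returns (read_id, 3' overhang).

    Anchoring is exact and gap-free: the overhang columns line up with the
    consensus positions immediately following the k-mer (substitution-only
    short-read model).  Zero-length overhangs are kept — the read supports
    the anchor but contributes no new columns.
    """
    out = []
    for rid, off, strand in index.lookup(kmer):
        oriented = reads[rid] if strand == "+" else revcomp(reads[rid])
        out.append((rid, oriented[off + index.k :]))
    return out


# ----------------------------------------------------------------------
# PWM
# ----------------------------------------------------------------------
@dataclass
class PWM:
    """Per-column nucleotide counts over anchored read overhangs."""

    counts: np.ndarray          # shape (4, n_cols), rows A,C,G,T
    support: np.ndarray         # reads covering each column

    @classmethod
    def from_overhangs(cls, overhangs: list[str]) -> "PWM":
        ncols = max((len(o) for o in overhangs), default=0)
        counts = np.zeros((4, ncols), dtype=np.int64)
        for o in overhangs:
            for j, b in enumerate(o):
                if b in _BASE_IDX:
                    counts[_BASE_IDX[b], j] += 1
        return cls(counts=counts, support=counts.sum(axis=0))

    @property
    def n_cols(self) -> int:
        return self.counts.shape[1]

    def consensus(self) -> str:
        """Argmax base per column; ties broken lexicographically (A<C<G<T)."""
        return "".join(_BASES[i] for i in self.counts.argmax(axis=0))

    def purity(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.support > 0, self.counts.max(axis=0) / self.support, 0.0)

    def column_tied(self) -> np.ndarray:
        top = self.counts.max(axis=0)
        return (self.counts == top).sum(axis=0) > 1


# ----------------------------------------------------------------------
# repeat periodicity
# ----------------------------------------------------------------------
def detect_repeat_unit(
    sequence: str,
    min_period: int = 1,
    max_period: int | None = None,
    repeat_id_threshold: float = 0.9,
    min_window: int = 12,
) -> tuple[str, int, int] | None:
    """Detect tandem periodicity at the 3' end of a sequence.

    Finds the smallest period ``p`` such that the trailing window of
    ``w = min(len, max(3p, min_window))`` columns matches itself shifted by
    ``p`` with identity >= ``repeat_id_threshold`` (at least two complete
    trailing copies required).  Returns ``(unit, period, phase)`` where the
    unit is a per-column majority consensus over the trailing complete
    copies and ``phase`` is the start of the last complete copy; ``None``
    when no period qualifies.
    """
    n = len(sequence)
    if n < 2 * max(min_period, 1):
        return None
    arr = np.frombuffer(sequence.encode(), dtype=np.uint8)
    hi = n // 2 if max_period is None else min(max_period, n // 2)
    for p in range(max(min_period, 1), hi + 1):
        w = min(n, max(3 * p, min_window))
        if w < 2 * p:
            continue
        tail = arr[n - w :]
        m = (tail[p:] == tail[:-p]).mean()
        if m >= repeat_id_threshold:
            return _majority_unit(sequence, p), p, n - p
    return None


def _majority_unit(sequence: str, p: int) -> str:
    """Majority-rule consensus over the trailing complete copies."""
    n = len(sequence)
    k = n // p
    copies = [sequence[n - (i + 1) * p : n - i * p] for i in range(min(k, 3))]
    if len(copies) == 1:
        return copies[0]
    cols = []
    for j in range(p):
        cnt = Counter(c[j] for c in copies)
        top = max(cnt.values())
        cols.append(min(b for b, v in cnt.items() if v == top))
    return "".join(cols)


def repeat_region_start(sequence: str, period: int, max_mismatch_frac: float = 0.05) -> int:
    """Walk the detected trailing periodicity 5'-wards to its first base.

    Full periods are stepped back while adjacent copies agree within
    ``max_mismatch_frac``; the final partial copy is walked base-exactly.
    The result depends only on the sequence content around the boundary,
    not on how far past it the 3' end happens to reach.
    """
    n = len(sequence)
    b = n - period
    budget = max(1, int(max_mismatch_frac * period))
    while b - period >= 0:
        prev = sequence[b - period : b]
        cur = sequence[b : b + period]
        mism = sum(1 for x, y in zip(prev, cur) if x != y)
        if mism <= budget:
            b -= period
        else:
            break
    while b > 0 and sequence[b - 1] == sequence[b - 1 + period]:
        b -= 1
    return b


# ----------------------------------------------------------------------
# consensus extension
# ----------------------------------------------------------------------
@dataclass
class ExtensionStep:
    kmer: str
    n_recruited: int
    n_accepted: int


@dataclass
class ExtensionState:
    consensus: str
    steps: list[ExtensionStep]
    stop_reason: str            # repeat_detected | support_exhausted | max_length
    repeat: tuple[str, int, int] | None = None  # (unit, period, phase) when detected


def extend_consensus(
    seed: str,
    index: KmerIndex,
    reads: dict[str, str],
    min_depth: int = 5,
    min_purity: float = 0.8,
    max_length: int = 50_000,
    min_unit: int = 50,
    repeat_id_threshold: float = 0.9,
    stall_shift: int = 20,
) -> ExtensionState:
    """Extend a seed 3'-wards by iterative k-mer recruitment and PWM voting.

    Per step: recruit reads anchored by the 3'-terminal k-mer, stack their
    overhangs into a PWM and accept leading columns while support >=
    ``min_depth`` and dominant-base fraction >= ``min_purity`` (a tie at the
    top count fails purity and stops the step).  Stops with
    ``repeat_detected`` once the trailing consensus shows tandem periodicity
    of at least ``min_unit`` nt over two complete copies, with
    ``support_exhausted`` when no column can be accepted, or with
    ``max_length``.
    """
    k = index.k
    if len(seed) < k:
        raise ValueError(f"seed shorter than k={k}")
    consensus = seed
    steps: list[ExtensionStep] = []
    while True:
        if len(consensus) >= max_length:
            return ExtensionState(consensus, steps, "max_length")
        rep = detect_repeat_unit(
            consensus[-min(len(consensus), 8000) :],   # cap the periodicity scan
            min_period=min_unit,
            repeat_id_threshold=repeat_id_threshold,
        )
        if rep is not None:
            _, p, _ = rep
            # canonicalise: keep exactly two copies past the repeat start and
            # report the unit phased at the repeat start, so the result does
            # not depend on recruitment block boundaries
            start = repeat_region_start(consensus, p)
            consensus = consensus[: min(len(consensus), start + 2 * p)]
            unit = consensus[start : start + p]
            return ExtensionState(consensus, steps, "repeat_detected", (unit, p, len(consensus) - p))

        # anchor the 3'-terminal k-mer; on a stall (depth dip or impure
        # column) retry with the anchor jittered a few bases 5'-wards,
        # keeping only overhang bases that agree with the existing consensus
        accepted = None
        for delta in range(0, stall_shift + 1):
            if len(consensus) < k + delta:
                break
            kmer = consensus[len(consensus) - k - delta : len(consensus) - delta]
            tail = consensus[len(consensus) - delta :] if delta else ""
            overhangs = []
            for _, o in recruit_and_align(kmer, index, reads):
                if delta == 0:
                    if o:
                        overhangs.append(o)
                elif len(o) > delta and o[:delta] == tail:
                    overhangs.append(o[delta:])
            if not overhangs:
                continue
            pwm = PWM.from_overhangs(overhangs)
            ok = (pwm.support >= min_depth) & (pwm.purity() >= min_purity) & ~pwm.column_tied()
            n_accept = int(np.argmin(ok)) if not ok.all() else pwm.n_cols
            if n_accept > 0:
                steps.append(ExtensionStep(kmer, len(overhangs), n_accept))
                accepted = pwm.consensus()[:n_accept]
                break
        if accepted is None:
            return ExtensionState(consensus, steps, "support_exhausted")
        consensus += accepted


# ----------------------------------------------------------------------
# seed discovery on contigs
# ----------------------------------------------------------------------
@dataclass
class SeedHit:
    contig_id: str
    start: int                  # nt, 0-based half-open, on the given strand's
    end: int                    # forward coordinates of the contig
    strand: str
    category: str               # NTD | CTD | repeat
    profile_id: str
    identity: float
    coverage: float             # aligned fraction of the profile


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    return aligner


def find_seeds(
    contigs: list[tuple[str, str]],
    profiles: list[tuple[str, str, str]],
    min_identity: float = 0.6,
    min_coverage: float = 0.4,
) -> list[SeedHit]:
    """Translated local-alignment search of domain profiles against contigs.

    ``profiles`` rows are ``(profile_id, category, aa_sequence)`` with
    category one of NTD/CTD/repeat.  Contigs are scanned in all six frames;
    hits must reach ``min_identity`` over an alignment covering at least
    ``min_coverage`` of the profile.  Coordinates are mapped back to the
    contig's forward strand in nucleotides.
    """
    aligner = _make_aligner()
    hits: list[SeedHit] = []
    for contig_id, seq in contigs:
        if set(seq.upper()) - set("ACGTN"):
            raise ValueError(f"contig {contig_id} is not nucleotide FASTA")
        for strand, oriented in (("+", seq), ("-", revcomp(seq))):
            for frame in range(3):
                sub = oriented[frame:]
                prot = str(Seq(sub[: len(sub) - len(sub) % 3]).translate())
                for pid, category, paa in profiles:
                    hit = _best_local_hit(aligner, paa, prot)
                    if hit is None:
                        continue
                    ident, cov, t_start, t_end = hit
                    if ident < min_identity or cov < min_coverage:
                        continue
                    nt_s = frame + 3 * t_start
                    nt_e = frame + 3 * t_end
                    if strand == "-":
                        nt_s, nt_e = len(seq) - nt_e, len(seq) - nt_s
                    hits.append(
                        SeedHit(contig_id, nt_s, nt_e, strand, category, pid, ident, cov)
                    )
    hits.sort(key=lambda h: (h.contig_id, -h.identity * h.coverage))
    return hits


def _best_local_hit(aligner, query: str, target: str):
    if not query or not target:
        return None
    try:
        aln = aligner.align(query, target)
        if len(aln) == 0:
            return None
        best = aln[0]
    except (ValueError, OverflowError):
        return None
    qa, ta = best[0], best[1]
    matches = sum(1 for a, b in zip(qa, ta) if a == b and a != "-")
    aligned = sum(1 for a, b in zip(qa, ta) if a != "-" and b != "-")
    if aligned == 0:
        return None
    ident = matches / aligned
    cov = aligned / len(query)
    t_start, t_end = best.aligned[1][0][0], best.aligned[1][-1][1]
    return ident, cov, int(t_start), int(t_end)


# ----------------------------------------------------------------------
# long-read copy-number estimation
# ----------------------------------------------------------------------
def _locate(query: str, target: str, max_id_loss: float):
    """Best approximate occurrence of query in target (edlib infix mode)."""
    res = edlib.align(query, target, mode="HW", task="locations")
    d = res["editDistance"]
    if d < 0 or d > max_id_loss * len(query):
        return None
    s, e = res["locations"][0]
    return s, e + 1, 1.0 - d / len(query)


def count_units_by_tiling(
    segment: str, unit: str, min_identity: float = 0.75
) -> int:
    """Count non-overlapping unit occurrences along a (noisy) segment."""
    pos, count = 0, 0
    u = len(unit)
    while len(segment) - pos >= 0.5 * u:
        window = segment[pos : pos + int(1.6 * u)]
        loc = _locate(unit, window, 1.0 - min_identity)
        if loc is None:
            break
        s, e, _ = loc
        count += 1
        pos += max(e, 1)
    return count


def estimate_iterations(
    ntd: str,
    unit: str,
    ctd: str,
    long_reads: dict[str, str],
    long_map_id: float = 0.75,
) -> tuple[int, list[str], bool, bool]:
    """Estimate tandem copy number from long reads.

    For each read (both strands tried) the NTD and CTD are located by
    approximate matching; reads containing NTD then CTD in order are
    *spanning* and the unit is tiled between the two anchors.  The estimate
    is the mode over spanning reads (ties resolved upward).  Without any
    spanning read the longest partial tiling is returned, flagged
    low-confidence.

    Returns ``(n_copies_estimate, spanning_read_ids, continuity_validated,
    low_confidence)``.
    """
    if not unit:
        raise ValueError("empty repeat unit")
    if not long_reads:
        raise ValueError("no long reads supplied")
    loss = 1.0 - long_map_id
    per_read: list[tuple[str, int]] = []
    partial_best = 0
    for rid, seq in long_reads.items():
        best = None
        for oriented in (seq, revcomp(seq)):
            n_loc = _locate(ntd, oriented, loss)
            c_loc = _locate(ctd, oriented, loss)
            if n_loc and c_loc and c_loc[0] >= n_loc[1]:
                n_units = count_units_by_tiling(
                    oriented[n_loc[1] : c_loc[0]], unit, long_map_id
                )
                if best is None or n_units > best:
                    best = n_units
            else:
                partial_best = max(partial_best, count_units_by_tiling(oriented, unit, long_map_id))
        if best is not None and best >= 1:
            per_read.append((rid, best))
    if per_read:
        counts = Counter(n for _, n in per_read)
        top = max(counts.values())
        estimate = max(n for n, v in counts.items() if v == top)
        return estimate, [rid for rid, _ in per_read], True, False
    return max(partial_best, 1), [], False, True


def polish_unit_with_short_reads(
    unit: str,
    short_reads: dict[str, str],
    max_read_divergence: float = 0.10,
    min_votes: int = 3,
) -> str:
    """Pileup-majority polish of a repeat-unit consensus.

    Short reads drawn from *all* copies of the array are aligned to the
    doubled unit (so junction-crossing reads are usable) and their bases
    vote per unit position, folding the two phases together.  Because copy
    mutations are independent, the across-copy majority converges on the
    ancestral unit even when the initial consensus came from as few as two
    collapsed copies.  Positions with fewer than ``min_votes`` aligned bases
    keep the input base.
    """
    if not unit:
        return unit
    u = len(unit)
    target = unit + unit
    votes = np.zeros((4, u), dtype=np.int64)
    for seq in short_reads.values():
        best = None
        for cand in (seq, revcomp(seq)):
            res = edlib.align(cand, target, mode="HW", task="path")
            d = res["editDistance"]
            if d < 0 or d > max_read_divergence * len(cand):
                continue
            if best is None or d < best[0]:
                best = (d, cand, res)
        if best is None:
            continue
        _, cand, res = best
        t_pos = res["locations"][0][0]
        q_pos = 0
        for n_str, op in _CIGAR_RE.findall(res["cigar"]):
            n = int(n_str)
            if op in "=X":
                for j in range(n):
                    b = cand[q_pos + j]
                    if b in _BASE_IDX:
                        votes[_BASE_IDX[b], (t_pos + j) % u] += 1
                t_pos += n
                q_pos += n
            elif op == "I":
                q_pos += n
            elif op == "D":
                t_pos += n
    out = []
    for j, base in enumerate(unit):
        col = votes[:, j]
        if col.sum() >= min_votes:
            top = col.max()
            out.append(min(_BASES[i] for i in range(4) if col[i] == top))
        else:
            out.append(base)
    return "".join(out)


# ----------------------------------------------------------------------
# curated gene assembly
# ----------------------------------------------------------------------
@dataclass
class CuratedGene:
    gene_id: str
    family_label: str | None
    ntd_nt: str
    ctd_nt: str
    repeat_unit_nt: str
    n_copies_estimate: int
    confidence: str                       # "long-read mode" | "partial span"
    spanning_long_read_ids: list[str] = field(default_factory=list)
    continuity_validated: bool = False
    ntd_partial: bool = False
    ctd_partial: bool = False
    extension_log: list[ExtensionStep] = field(default_factory=list)


class UnitConflictError(ValueError):
    """NTD-side and CTD-side extensions disagree about the repeat unit."""

    def __init__(self, unit_a: str, unit_b: str, ident: float):
        self.unit_a, self.unit_b, self.identity = unit_a, unit_b, ident
        super().__init__(
            f"conflicting repeat units (cyclic identity {ident:.2f} < 0.9): "
            f"NTD-side {unit_a[:40]}... vs CTD-side {unit_b[:40]}..."
        )


def assemble_curated_gene(
    gene_id: str,
    ntd_nt: str | None,
    ctd_nt: str | None,
    unit_ntd_side: str | None,
    unit_ctd_side: str | None,
    iteration_result: tuple[int, list[str], bool, bool] | None,
    family_label: str | None = None,
    extension_log: list[ExtensionStep] | None = None,
) -> CuratedGene:
    """Merge seed/extension/iteration evidence into one curated record.

    Units recovered from the two extension directions must agree (cyclic
    identity >= 0.9, strand-aware); otherwise a :class:`UnitConflictError`
    listing both is raised.  Missing terminals are kept as empty sequences
    flagged partial.
    """
    unit = unit_ntd_side or unit_ctd_side
    if unit_ntd_side and unit_ctd_side:
        ident = cyclic_identity(unit_ntd_side, unit_ctd_side)
        if ident < 0.9:
            raise UnitConflictError(unit_ntd_side, unit_ctd_side, ident)
    if iteration_result is not None:
        n_est, span_ids, continuous, low_conf = iteration_result
    else:
        n_est, span_ids, continuous, low_conf = 1, [], False, True
    return CuratedGene(
        gene_id=gene_id,
        family_label=family_label,
        ntd_nt=ntd_nt or "",
        ctd_nt=ctd_nt or "",
        repeat_unit_nt=unit or "",
        n_copies_estimate=max(n_est, 1),
        confidence="partial span" if low_conf else "long-read mode",
        spanning_long_read_ids=span_ids,
        continuity_validated=continuous,
        ntd_partial=not ntd_nt,
        ctd_partial=not ctd_nt,
        extension_log=extension_log or [],
    )


def curate_gene(
    contigs: list[tuple[str, str]],
    short_reads: dict[str, str],
    long_reads: dict[str, str],
    profiles: list[tuple[str, str, str]],
    gene_id: str = "gene",
    family_label: str | None = None,
    k: int = 100,
    min_depth: int = 5,
    min_purity: float = 0.8,
    min_unit: int = 50,
    polish_unit: bool = True,
) -> CuratedGene:
    """End-to-end curation of one gene from contigs + short + long reads.

    Seeds come from profile hits on the contigs.  The NTD-side seed is
    extended 3'-wards through the short reads; the repeat unit is taken from
    detected trailing periodicity when the extension reaches two full
    copies, and otherwise from the periodicity of the contig region between
    the terminal hits (assemblers leave a collapsed copy or two there, and
    near-identical copies stall PWM extension by design).  Copy number and
    NTD-repeats-CTD continuity always come from the long reads.
    """
    hits = find_seeds(contigs, profiles)
    by_cat: dict[str, SeedHit] = {}
    for h in hits:
        if h.category not in by_cat:
            by_cat[h.category] = h
    contig_seqs = dict(contigs)

    def oriented_contig(hit: SeedHit) -> tuple[str, int, int]:
        seq = contig_seqs[hit.contig_id]
        if hit.strand == "+":
            return seq, hit.start, hit.end
        return revcomp(seq), len(seq) - hit.end, len(seq) - hit.start

    ntd_nt = ctd_nt = None
    unit_n = unit_c = None
    ext_log: list[ExtensionStep] = []

    index = build_kmer_screen(short_reads, k) if short_reads else None

    n_hit = by_cat.get("NTD")
    c_hit = by_cat.get("CTD")

    if n_hit is not None:
        cseq, s, e = oriented_contig(n_hit)
        ntd_nt = cseq[:e]
        if index is not None and len(ntd_nt) >= k:
            state = extend_consensus(
                ntd_nt, index, short_reads,
                min_depth=min_depth, min_purity=min_purity, min_unit=min_unit,
            )
            ext_log.extend(state.steps)
            if state.stop_reason == "repeat_detected" and state.repeat is not None:
                unit_n, period, _ = state.repeat
                ntd_nt = state.consensus[: repeat_region_start(state.consensus, period)]
            # a stall inside the array leaves a partial repeat walk on the
            # consensus; the profile-hit boundary is the cleaner NTD end
    if c_hit is not None:
        cseq, s, e = oriented_contig(c_hit)
        ctd_nt = cseq[s:]
        rc_seed = revcomp(ctd_nt)
        if index is not None and len(rc_seed) >= k:
            state = extend_consensus(
                rc_seed, index, short_reads,
                min_depth=min_depth, min_purity=min_purity, min_unit=min_unit,
            )
            ext_log.extend(state.steps)
            if state.stop_reason == "repeat_detected" and state.repeat is not None:
                u, period, _ = state.repeat
                unit_c = revcomp(u)
                ctd_nt = revcomp(state.consensus[: repeat_region_start(state.consensus, period)])

    # fall back to collapsed repeat copies left on the contig between the
    # terminal hits, or to explicit repeat-category seeds
    if unit_n is None and unit_c is None:
        seg = None
        if n_hit is not None and c_hit is not None and n_hit.contig_id == c_hit.contig_id:
            cseq, _, ne = oriented_contig(n_hit)
            _, cs, _ = oriented_contig(c_hit)
            if cs > ne:
                seg = cseq[ne:cs]
        if seg is None and "repeat" in by_cat:
            h = by_cat["repeat"]
            cseq, s, e = oriented_contig(h)
            seg = cseq[s:e]
        if seg:
            rep = detect_repeat_unit(seg, min_period=min_unit)
            if rep is not None:
                unit_n = rep[0]
        if unit_n is None and seg and n_hit is not None and c_hit is not None:
            # exactly two collapsed copies with no trailing partial copy can
            # also be read off as half the inter-terminal segment
            half = len(seg) // 2
            if half >= min_unit and cyclic_identity(seg[:half], seg[half:]) >= 0.9:
                unit_n = seg[:half]

    if polish_unit and short_reads:
        if unit_n:
            unit_n = polish_unit_with_short_reads(unit_n, short_reads)
        if unit_c:
            unit_c = polish_unit_with_short_reads(unit_c, short_reads)

    iteration = None
    if (unit_n or unit_c) and ntd_nt and ctd_nt and long_reads:
        iteration = estimate_iterations(ntd_nt, (unit_n or unit_c), ctd_nt, long_reads)
    elif not long_reads:
        warnings.warn(f"{gene_id}: no long reads; copy number left low-confidence")

    return assemble_curated_gene(
        gene_id, ntd_nt, ctd_nt, unit_n, unit_c, iteration,
        family_label=family_label, extension_log=ext_log,
    )
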