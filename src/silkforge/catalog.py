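"""Annotation of spidroin sequences: start codon, domains, motifs, catalogue.

Start-codon selection scores each candidate ATG by its Kozak context
(purine at -3 and G at +4 are the strong determinants) combined with a
signal-peptide heuristic on the encoded N-terminus — secreted silk proteins
begin with a short charged stretch followed by a hydrophobic core, so the
true start is the ATG whose downstream peptide looks most like a secretion
signal.  The heuristic is a deterministic in-repo stand-in built on
Kyte-Doolittle hydropathy.

Domain segmentation locates the non-repetitive terminal domains by local
alignment against family terminal profiles and decomposes the interval
between them into tandem copies; motif scanning counts the silk motif
inventory (poly-A runs, GGX, GPGGX, GPSS and the QQ/TT/SS spacer
dipeptides) with a longest-motif-wins precedence and greedy left-to-right
non-overlap.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from Bio.SeqUtils.ProtParamData import kd as KYTE_DOOLITTLE

from ._seq import translate
from .smoc import SeedHit, detect_repeat_unit, find_seeds

_DNA = set("ACGTN")


# ----------------------------------------------------------------------
# start-codon selection
# ----------------------------------------------------------------------
@dataclass
class StartCandidate:
    position: int
    kozak_score: float
    signal_score: float
    orf_aa: int

    @property
    def score(self) -> float:
        return self.kozak_score + self.signal_score


def kozak_score(cdna: str, atg_pos: int) -> float:
    """Positional weight of the Kozak context around one ATG.

    Purine at -3 scores 2, G at +4 scores 1, with half-point bonuses for the
    common C at -1/-2; absent positions (ATG at the sequence edge) score 0.
    """
    score = 0.0
    if atg_pos >= 3 and cdna[atg_pos - 3] in "AG":
        score += 2.0
    if atg_pos + 3 < len(cdna) and cdna[atg_pos + 3] == "G":
        score += 1.0
    if atg_pos >= 1 and cdna[atg_pos - 1] == "C":
        score += 0.5
    if atg_pos >= 2 and cdna[atg_pos - 2] == "C":
        score += 0.5
    return score


def signal_peptide_score(protein_nterm: str, window: int = 9) -> float:
    """Secretion-signal likelihood of an N-terminal peptide, bounded [-1, 1.3].

    Maximum sliding-window (width 9) mean Kyte-Doolittle hydropathy over
    residues 1-30, scaled by the table maximum (4.5), plus 0.3 when a
    positively charged residue (K/R) occurs in the first five — the n-region
    charge of classical signal peptides.  Residues beyond 30 never change
    the score.
    """
    region = protein_nterm[:30]
    vals = [KYTE_DOOLITTLE.get(aa, 0.0) for aa in region]
    if len(vals) < window:
        vals = vals + [0.0] * (window - len(vals))
    arr = np.array(vals)
    means = np.convolve(arr, np.ones(window) / window, mode="valid")
    hyd = float(np.clip(means.max() / 4.5, -1.0, 1.0))
    charged = any(aa in "KR" for aa in region[:5])
    return hyd + (0.3 if charged else 0.0)


def select_start_codon(
    cdna: str, min_orf_aa: int = 50, signal_weight: float = 1.0
) -> tuple[int, float, list[StartCandidate]]:
    """Choose the initiation ATG of a cDNA.

    Every ATG opening an ORF of at least ``min_orf_aa`` codons is scored by
    ``kozak_score`` plus ``signal_weight`` times the signal-peptide score of
    the first 30 encoded residues; all candidates are returned for audit.
    Raises ``ValueError`` when no qualifying ATG exists.
    """
    cdna = cdna.upper()
    candidates: list[StartCandidate] = []
    pos = cdna.find("ATG")
    while pos != -1:
        prot = translate(cdna[pos:])
        orf = prot.index("*") if "*" in prot else len(prot)
        if orf >= min_orf_aa:
            candidates.append(
                StartCandidate(
                    position=pos,
                    kozak_score=kozak_score(cdna, pos),
                    signal_score=signal_weight * signal_peptide_score(prot[1:31]),
                    orf_aa=orf,
                )
            )
        pos = cdna.find("ATG", pos + 1)
    if not candidates:
        raise ValueError("no ATG opening a sufficiently long ORF")
    best = max(candidates, key=lambda c: (c.score, -c.position))
    return best.position, best.score, candidates


# ----------------------------------------------------------------------
# motif scanning
# ----------------------------------------------------------------------
#: scanning precedence: longer, more specific motifs first
MOTIF_CLASSES = ("GPGGX", "GPSS", "polyA", "GGX", "QQ", "TT", "SS")


@dataclass
class MotifProfile:
    counts: dict[str, int] = field(default_factory=lambda: {m: 0 for m in MOTIF_CLASSES})

    def total(self) -> int:
        return sum(self.counts.values())


def _match_motif(seq: str, i: int, cls: str, min_run: int) -> int:
    """Length consumed by motif class ``cls`` anchored at ``i`` (0 = no match)."""
    if cls == "polyA":
        j = i
        while j < len(seq) and seq[j] == "A":
            j += 1
        return j - i if j - i >= min_run else 0
    if cls == "GPGGX":
        return 5 if seq[i : i + 4] == "GPGG" and i + 4 < len(seq) else 0
    if cls == "GPSS":
        return 4 if seq[i : i + 4] == "GPSS" else 0
    if cls == "GGX":
        return 3 if seq[i : i + 2] == "GG" and i + 2 < len(seq) else 0
    if cls in ("QQ", "TT", "SS"):
        return 2 if seq[i : i + 2] == cls else 0
    raise ValueError(cls)


def scan_motifs(aa_sequence: str, min_run: int = 4) -> MotifProfile:
    """Greedy left-to-right, non-overlapping motif inventory.

    At each position the highest-precedence matching class consumes its
    span; maximal runs of spacer dipeptides therefore count floor(run/2)
    and a poly-A run of length >= ``min_run`` counts once however long.
    """
    prof = MotifProfile()
    i = 0
    n = len(aa_sequence)
    while i < n:
        for cls in MOTIF_CLASSES:
            used = _match_motif(aa_sequence, i, cls, min_run)
            if used:
                prof.counts[cls] += 1
                i += used
                break
        else:
            i += 1
    return prof


# ----------------------------------------------------------------------
# domain segmentation
# ----------------------------------------------------------------------
@dataclass
class DomainAnnotation:
    gene_id: str
    family: str | None
    start_codon_pos: int
    ntd: tuple[int, int]
    rtd: tuple[int, int]
    ctd: tuple[int, int]
    unit_len_mean: float
    n_copies: int
    ntd_partial: bool = False
    ctd_partial: bool = False
    motifs: dict[str, int] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)


def segment_domains(
    sequence: str,
    terminal_profiles: list[tuple[str, str, str]],
    gene_id: str = "gene",
    family: str | None = None,
    min_unit: int = 30,
    partial_coverage: float = 0.8,
) -> DomainAnnotation:
    """Locate NTD/RTD/CTD on a coding sequence (nt, or aa auto-detected).

    Terminal domains are placed by the best local alignment to the supplied
    family profiles (``(id, NTD|CTD, aa)`` rows); the repetitive domain is
    the interval between them, decomposed into tandem copies by trailing
    periodicity.  A terminal whose profile alignment covers less than
    ``partial_coverage`` of the profile is flagged partial; a missing hit
    yields a zero-length domain flagged partial.
    """
    seq = sequence.upper()
    is_nt = not (set(seq) - _DNA)
    scale = 1 if not is_nt else 3   # aa hits map to nt coordinates on nt input
    terminals = [p for p in terminal_profiles if p[1] in ("NTD", "CTD")]
    best: dict[str, SeedHit] = {}
    if is_nt:
        nt = seq
        for h in find_seeds([(gene_id, nt)], terminals):
            if h.strand == "+" and h.category not in best:
                best[h.category] = h
    else:
        # amino-acid input: align profiles directly, coordinates in residues
        from .smoc import _best_local_hit, _make_aligner

        nt = seq
        aligner = _make_aligner()
        scored = []
        for pid, category, paa in terminals:
            hit = _best_local_hit(aligner, paa, seq)
            if hit is None:
                continue
            ident, cov, s, e = hit
            if ident >= 0.6 and cov >= 0.4:
                scored.append(SeedHit(gene_id, s, e, "+", category, pid, ident, cov))
        scored.sort(key=lambda h: -h.identity * h.coverage)
        for h in scored:
            if h.category not in best:
                best[h.category] = h
    n_hit, c_hit = best.get("NTD"), best.get("CTD")
    ntd_iv = (0, n_hit.end) if n_hit else (0, 0)
    ctd_iv = (c_hit.start, len(nt)) if c_hit else (len(nt), len(nt))
    rtd_iv = (ntd_iv[1], ctd_iv[0])
    unit_len, n_copies = 0.0, 0
    seg = nt[rtd_iv[0] : rtd_iv[1]]
    if seg:
        rep = detect_repeat_unit(seg, min_period=min_unit if is_nt else max(min_unit // 3, 5))
        if rep is not None:
            _, p, _ = rep
            n_copies = max(1, round(len(seg) / p))
            unit_len = len(seg) / n_copies
    start_pos = 0
    if is_nt:
        try:
            start_pos, _, _ = select_start_codon(nt)
        except ValueError:
            pass
    motifs = scan_motifs(translate(seg) if is_nt else seg) if seg else MotifProfile()
    return DomainAnnotation(
        gene_id=gene_id,
        family=family,
        start_codon_pos=start_pos,
        ntd=ntd_iv,
        rtd=rtd_iv,
        ctd=ctd_iv,
        unit_len_mean=unit_len,
        n_copies=n_copies,
        ntd_partial=(n_hit is None or n_hit.coverage < partial_coverage),
        ctd_partial=(c_hit is None or c_hit.coverage < partial_coverage),
        motifs=dict(motifs.counts),
    )


# ----------------------------------------------------------------------
# catalogue table
# ----------------------------------------------------------------------
def catalog_table(annotations: list[DomainAnnotation]) -> pd.DataFrame:
    """One row per gene plus per-family mean rows (family, ``species='mean'``)."""
    cols = ["gene_id", "family", "ntd_len", "unit_len_mean", "n_copies", "ctd_len", "flags"]
    rows = []
    for a in annotations:
        flags = ";".join(
            f for f, on in (("ntd_partial", a.ntd_partial), ("ctd_partial", a.ctd_partial)) if on
        )
        rows.append(
            {
                "gene_id": a.gene_id,
                "family": a.family or "NA",
                "ntd_len": a.ntd[1] - a.ntd[0],
                "unit_len_mean": a.unit_len_mean,
                "n_copies": a.n_copies,
                "ctd_len": a.ctd[1] - a.ctd[0],
                "flags": flags,
            }
        )
    df = pd.DataFrame(rows, columns=cols)
    if len(df):
        means = (
            df.groupby("family", sort=True)[["ntd_len", "unit_len_mean", "n_copies", "ctd_len"]]
            .mean()
            .reset_index()
        )
        means.insert(0, "gene_id", means["family"] + "_mean")
        means["flags"] = "family_mean"
        df = pd.concat([df, means], ignore_index=True)
    return df


def write_gff3(annotations: list[DomainAnnotation], path) -> None:
    """Domain intervals as GFF3 (1-based, closed intervals)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for a in annotations:
            for name, (s, e) in (("NTD", a.ntd), ("RTD", a.rtd), ("CTD", a.ctd)):
                if e <= s:
                    continue
                fh.write(
                    f"{a.gene_id}\tsilkforge\t{name}\t{s + 1}\t{e}\t.\t+\t.\t"
                    f"ID={a.gene_id}_{name};family={a.family or 'NA'}\n"
                )


def default_terminal_profiles(families=None) -> list[tuple[str, str, str]]:
    """Family terminal-domain amino-acid profiles from the generative templates.

    Deterministic, synthetic stand-ins for curated terminal profiles; users
    with real curated spidroin terminals should pass their own FASTA-derived
    profiles instead.
    """
    from .genes import FAMILY_NAMES, SpidroinGeneModel

    families = families or FAMILY_NAMES
    out = []
    for fam in families:
        model = SpidroinGeneModel.from_family(fam, species_divergence=0.0)
        out.append((f"{fam}_NTD", "NTD", translate(model.ntd_nt)))
        out.append((f"{fam}_CTD", "CTD", translate(model.ctd_nt)))
    return out
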