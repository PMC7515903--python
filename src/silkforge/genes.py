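"""Generative models of spidroin gene architecture.

A spidroin gene is modelled as a spliceless coding sequence
``NTD + n x (repeat unit) + CTD``: non-repetitive N- and C-terminal domains
flanking a long tandem array whose unit carries a family-specific motif
vocabulary (poly-alanine runs in major-ampullate and cribellar silks, GGX /
GPGGX in flagelliform-type silks, spacer TT/SS dipeptides, ...).  The nine
families modelled here cover the gland repertoire of orb-weaving spiders;
the cribellar spidroin (CrSp) template carries the unusually long (>2 kb)
N-terminal domain and ~1 kb repeat unit reported for cribellate species,
with 11 tandem copies, while pseudoflagelliform spidroin (Pflag) has the
short ~200 nt unit typical of that family.

Every generated sequence is free of stop codons in all three frames (see
:mod:`silkforge._seq`), so tandem arrays whose unit length is not a multiple
of three still translate without internal stops.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from ._seq import (
    SAFE_RESIDUES,
    encode_protein,
    mutate_keeping_frame_open,
    translate,
)

FAMILY_NAMES = (
    "MaSp",
    "MiSp",
    "AcSp",
    "CySp",
    "PySp",
    "CrSp",
    "Pflag",
    "Flag",
    "AgSp",
)


@dataclass(frozen=True)
class FamilyTemplate:
    """Architecture defaults and motif vocabulary for one spidroin family."""

    name: str
    ntd_len: int        # nt, codon multiple
    unit_len: int       # nt, may be any length
    ctd_len: int        # nt, codon multiple
    n_copies: int
    motifs: tuple[str, ...]
    background: dict[str, float]  # amino-acid frequencies of non-motif body


def _bg(**freqs: float) -> dict[str, float]:
    total = sum(freqs.values())
    return {aa: f / total for aa, f in freqs.items()}


# Architecture scales follow the catalogued genes: CrSp CTD 962 nt and unit
# 1009 nt on average with at least 11 tandem copies and an NTD over 2 kb;
# AcSp unit 1124 nt; Pflag units around 200 nt; remaining NTDs average
# ~500 nt.  Copy numbers outside CrSp are round figures in the 8-15 range
# typical for the families.
FAMILY_TEMPLATES: dict[str, FamilyTemplate] = {
    t.name: t
    for t in (
        FamilyTemplate(
            "MaSp", 504, 210, 306, 12,
            ("AAAAAA", "GGA", "GGQ", "GGL"),
            _bg(G=0.35, A=0.25, Q=0.12, S=0.08, L=0.06, P=0.05, R=0.04, E=0.05),
        ),
        FamilyTemplate(
            "MiSp", 504, 300, 306, 10,
            ("GGA", "GGQ", "AAAA", "TT"),
            _bg(G=0.32, A=0.28, S=0.10, Q=0.10, T=0.08, L=0.05, R=0.04, D=0.03),
        ),
        FamilyTemplate(
            "AcSp", 504, 1124, 306, 8,
            ("SS", "TT", "SQ", "AL"),
            _bg(S=0.24, A=0.18, Q=0.12, T=0.10, L=0.10, G=0.08, N=0.08, V=0.05, I=0.05),
        ),
        FamilyTemplate(
            "CySp", 504, 600, 306, 8,
            ("SS", "AA", "SQ", "FA"),
            _bg(S=0.26, A=0.22, Q=0.14, N=0.08, T=0.08, L=0.08, F=0.06, G=0.08),
        ),
        FamilyTemplate(
            "PySp", 504, 600, 306, 9,
            ("QQ", "AA", "PA", "SQ"),
            _bg(Q=0.22, A=0.20, P=0.12, S=0.14, E=0.08, L=0.08, G=0.08, R=0.08),
        ),
        FamilyTemplate(
            "CrSp", 2100, 1009, 962, 11,
            ("AAAAA", "TT", "SS", "GA"),
            _bg(A=0.26, S=0.18, G=0.14, T=0.12, Q=0.10, L=0.07, V=0.06, E=0.07),
        ),
        FamilyTemplate(
            "Pflag", 504, 200, 306, 15,
            ("GGX", "GPSS", "QQ"),
            _bg(G=0.30, P=0.16, S=0.16, Q=0.14, A=0.10, V=0.07, E=0.07),
        ),
        FamilyTemplate(
            "Flag", 504, 400, 306, 14,
            ("GGX", "GPGGX", "GPGGA"),
            _bg(G=0.38, P=0.18, A=0.12, S=0.10, V=0.08, Q=0.08, E=0.06),
        ),
        FamilyTemplate(
            "AgSp", 504, 900, 306, 8,
            ("QQ", "TT", "GN"),
            _bg(N=0.18, Q=0.16, G=0.14, T=0.12, S=0.10, I=0.10, D=0.08, K=0.06, E=0.06),
        ),
    )
}


@dataclass
class SpidroinGeneModel:
    """Ground-truth description of one gene to simulate."""

    family_label: str
    ntd_nt: str
    ctd_nt: str
    repeat_unit_nt: str
    n_copies: int
    per_copy_divergence: float = 0.005
    motif_vocabulary: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.n_copies < 2:
            raise ValueError("n_copies must be >= 2: repeat detection is undefined below that")
        if not 0 <= self.per_copy_divergence <= 0.1:
            raise ValueError("per_copy_divergence must be in [0, 0.1]")
        bad = [m for m in self.motif_vocabulary if set(m) - SAFE_RESIDUES - {"X"}]
        if bad:
            raise ValueError(
                f"motifs {bad} contain residues whose codons can create stop "
                "codons in shifted frames (C/M/W/Y are excluded)"
            )

    # ------------------------------------------------------------------
    @classmethod
    def from_family(
        cls,
        family: str,
        *,
        species_seed: int = 0,
        species_divergence: float = 0.02,
        per_copy_divergence: float = 0.005,
        ntd_len: int | None = None,
        unit_len: int | None = None,
        ctd_len: int | None = None,
        n_copies: int | None = None,
    ) -> "SpidroinGeneModel":
        """Build a species-level gene model from the family template.

        The family ancestor is deterministic (seeded by the family name), so
        different species of the same family share recognisably homologous
        terminal domains; ``species_seed``/``species_divergence`` then add the
        species-level sequence divergence observed within each family.
        """
        tmpl = FAMILY_TEMPLATES[family]
        anc_rng = np.random.default_rng(zlib.crc32(f"silkforge:{family}".encode()) % 2**31)
        ntd_len = tmpl.ntd_len if ntd_len is None else ntd_len
        unit_len = tmpl.unit_len if unit_len is None else unit_len
        ctd_len = tmpl.ctd_len if ctd_len is None else ctd_len
        n_copies = tmpl.n_copies if n_copies is None else n_copies

        ntd = _design_terminal(ntd_len, tmpl, anc_rng, signal_peptide=True)
        ctd = _design_terminal(ctd_len, tmpl, anc_rng, signal_peptide=False)
        unit = _design_unit(unit_len, tmpl, anc_rng)

        if species_divergence > 0:
            sp_rng = np.random.default_rng(species_seed)
            ntd = mutate_keeping_frame_open(ntd, species_divergence, sp_rng)
            ctd = mutate_keeping_frame_open(ctd, species_divergence, sp_rng)
            unit = _fix_unit_junction(
                mutate_keeping_frame_open(unit, species_divergence, sp_rng)
            )
        return cls(
            family_label=family,
            ntd_nt=ntd,
            ctd_nt=ctd,
            repeat_unit_nt=unit,
            n_copies=n_copies,
            per_copy_divergence=per_copy_divergence,
            motif_vocabulary=tmpl.motifs,
        )


@dataclass
class GeneRecord:
    """A realised gene: CDS plus the truth table used by recovery tests."""

    gene_id: str
    cds: str
    domains: dict[str, tuple[int, int]]  # 0-based half-open NTD/RTD/CTD
    n_copies: int
    model: SpidroinGeneModel = field(repr=False)

    @property
    def ntd(self) -> str:
        s, e = self.domains["NTD"]
        return self.cds[s:e]

    @property
    def rtd(self) -> str:
        s, e = self.domains["RTD"]
        return self.cds[s:e]

    @property
    def ctd(self) -> str:
        s, e = self.domains["CTD"]
        return self.cds[s:e]

    @property
    def protein(self) -> str:
        return translate(self.cds)

    def truth_rows(self) -> list[tuple[str, str, int, int, int]]:
        return [
            (self.gene_id, dom, s, e, self.n_copies)
            for dom, (s, e) in self.domains.items()
        ]


# ----------------------------------------------------------------------
def _sample_background(n: int, tmpl: FamilyTemplate, rng: np.random.Generator) -> str:
    aas = list(tmpl.background)
    probs = np.array([tmpl.background[a] for a in aas])
    return "".join(rng.choice(aas, size=n, p=probs))


def _expand_motif(motif: str, rng: np.random.Generator) -> str:
    """'X' in a motif is a wildcard filled from {A,S,Q,V,L}."""
    return "".join(
        "ASQVL"[rng.integers(5)] if c == "X" else c for c in motif
    )


def _design_aa(n: int, tmpl: FamilyTemplate, rng: np.random.Generator, motif_every: int = 8) -> str:
    """Interleave motifs with background residues up to length ``n``."""
    out: list[str] = []
    length = 0
    while length < n:
        spacer = _sample_background(int(rng.integers(2, motif_every)), tmpl, rng)
        motif = _expand_motif(tmpl.motifs[rng.integers(len(tmpl.motifs))], rng)
        out.append(spacer)
        out.append(motif)
        length += len(spacer) + len(motif)
    return "".join(out)[:n]


def _design_terminal(
    nt_len: int, tmpl: FamilyTemplate, rng: np.random.Generator, signal_peptide: bool
) -> str:
    # any nt length is safe: the encoding is stop-proof in all frames
    n_aa = -(-nt_len // 3)
    body = _sample_background(n_aa, tmpl, rng)
    if signal_peptide:
        # secretion signal: Met, a positive charge, then a hydrophobic core
        core = "".join("LVFI"[rng.integers(4)] for _ in range(13))
        body = "K" + core + "A" + body[15:]
        nt = "ATG" + encode_protein(body[: n_aa - 1], rng)
    else:
        nt = encode_protein(body, rng)
    return nt[:nt_len]


def _fix_unit_junction(unit: str) -> str:
    # a unit ending in T could form TA/TG across the copy junction
    if unit.endswith("T"):
        unit = unit[:-1] + "C"
    return unit


def _design_unit(nt_len: int, tmpl: FamilyTemplate, rng: np.random.Generator) -> str:
    n_aa = -(-nt_len // 3)
    aa = _design_aa(n_aa, tmpl, rng)
    return _fix_unit_junction(encode_protein(aa, rng)[:nt_len])


# ----------------------------------------------------------------------
def generate_gene(model: SpidroinGeneModel, seed: int, gene_id: str | None = None) -> GeneRecord:
    """Realise a gene model into a CDS plus a domain truth table.

    Each repeat copy receives independent substitutions at
    ``per_copy_divergence``; coordinates are 0-based half-open.  The same
    model and seed always give the same CDS.
    """
    rng = np.random.default_rng(seed)
    copies = [
        _fix_unit_junction(
            mutate_keeping_frame_open(model.repeat_unit_nt, model.per_copy_divergence, rng)
        )
        for _ in range(model.n_copies)
    ]
    rtd = "".join(copies)
    cds = model.ntd_nt + rtd + model.ctd_nt
    domains = {
        "NTD": (0, len(model.ntd_nt)),
        "RTD": (len(model.ntd_nt), len(model.ntd_nt) + len(rtd)),
        "CTD": (len(model.ntd_nt) + len(rtd), len(cds)),
    }
    prot = translate(cds)
    if "*" in prot:
        raise AssertionError("internal stop codon in generated CDS (generator bug)")
    if gene_id is None:
        gene_id = f"{model.family_label}_seed{seed}"
    return GeneRecord(gene_id=gene_id, cds=cds, domains=domains, n_copies=model.n_copies, model=model)


def make_contig_fixtures(
    genes: list[GeneRecord], policy: str = "repeat_collapse"
) -> list[tuple[str, str]]:
    """Emit assembler-like contigs for the curation stage.

    ``perfect``         — contig per gene equal to the full CDS.
    ``repeat_collapse`` — terminals flanking at most two repeat copies, the
                          way de Bruijn assemblers collapse tandem arrays.
    ``terminal_only``   — separate NTD and CTD fragments, no repeat copies.
    """
    out: list[tuple[str, str]] = []
    for g in genes:
        ntd_s, ntd_e = g.domains["NTD"]
        rtd_s, rtd_e = g.domains["RTD"]
        unit = len(g.model.repeat_unit_nt)
        if policy == "perfect":
            out.append((f"{g.gene_id}|perfect", g.cds))
        elif policy == "repeat_collapse":
            keep = min(2, g.n_copies) * unit
            out.append(
                (f"{g.gene_id}|collapsed", g.cds[: rtd_s + keep] + g.cds[rtd_e:])
            )
        elif policy == "terminal_only":
            out.append((f"{g.gene_id}|NTD", g.cds[ntd_s:ntd_e]))
            out.append((f"{g.gene_id}|CTD", g.cds[rtd_e:]))
        else:
            raise ValueError(f"unknown fragmentation policy: {policy!r}")
    return out


def default_gene_set(
    families: tuple[str, ...] = FAMILY_NAMES,
    n_species: int = 6,
    seed: int = 0,
    **model_kwargs,
) -> dict[tuple[str, str], GeneRecord]:
    """A catalogue-shaped gene set: one gene per (species, family)."""
    out: dict[tuple[str, str], GeneRecord] = {}
    for si in range(n_species):
        species = f"sp{si + 1}"
        for fi, fam in enumerate(families):
            model = SpidroinGeneModel.from_family(
                fam, species_seed=seed * 10007 + si * 101 + fi, **model_kwargs
            )
            out[(species, fam)] = generate_gene(
                model, seed=seed * 7919 + si * 211 + fi * 17, gene_id=f"{species}_{fam}"
            )
    return out
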