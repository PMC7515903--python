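"""End-to-end orchestration: simulate -> curate -> annotate -> analyse.

A run is driven by one :class:`RunConfig` (loadable from YAML) with a
single global seed; every stage writes into its own subdirectory of the
run directory plus a ``.stage.json`` manifest (stage parameters, input
checksums, package version).  A rerun with an identical manifest reuses
the cached stage output, and identical configs give byte-identical
outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from ._seq import translate
from .catalog import catalog_table, segment_domains, write_gff3
from .composition import CompositionMatrix, cluster, correlation_matrix, plot_heatmap
from .genes import FAMILY_NAMES, SpidroinGeneModel, generate_gene, make_contig_fixtures
from .phylo import bootstrap, monophyly_report, trim_terminals, align_terminals
from .proteomics import match_observations, empai_table, region_report
from .reads import ReadSimConfig, simulate_long_reads, simulate_short_reads, write_fastq
from .smoc import curate_gene
from .webproteome import PeptideObservationModel, simulate_peptide_observations

log = logging.getLogger("silkforge")

STAGES = ("simulate", "curate", "annotate", "compose", "phylo", "proteome")


@dataclass
class RunConfig:
    outdir: str = "silkforge_run"
    seed: int = 0
    n_species: int = 2
    families: tuple[str, ...] = FAMILY_NAMES
    curate_families: tuple[str, ...] = ("CrSp", "Pflag")
    stages: tuple[str, ...] = STAGES
    # module parameters surfaced in config
    k: int = 100
    min_depth: int = 5
    min_purity: float = 0.8
    coverage_short: float = 30.0
    coverage_long: float = 20.0
    short_error_rate: float = 0.001
    long_error_rate: float = 0.10
    bootstrap_reps: int = 100

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - fields
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("families", "curate_families", "stages"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("families", "curate_families", "stages"):
            d[key] = list(d[key])
        return d


def _sha(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage_key(cfg: RunConfig, stage: str, inputs: list[Path]) -> str:
    payload = {
        "stage": stage,
        "version": __version__,
        "config": cfg.to_dict(),
        "inputs": {p.name: _sha(p) for p in sorted(inputs)},
    }
    return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()


def _cached(stage_dir: Path, key: str) -> bool:
    mf = stage_dir / ".stage.json"
    if mf.exists():
        try:
            return json.loads(mf.read_text())["key"] == key
        except (json.JSONDecodeError, KeyError):
            return False
    return False


def _mark(stage_dir: Path, key: str) -> None:
    (stage_dir / ".stage.json").write_text(json.dumps({"key": key, "version": __version__}))


def read_fasta(path) -> list[tuple[str, str]]:
    from Bio import SeqIO

    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(records: list[tuple[str, str]], path) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def read_fastq_strict(path) -> dict[str, str]:
    """FASTQ reader that reports the offending file and line on corruption."""
    reads: dict[str, str] = {}
    with open(path) as fh:
        lines = fh.read().splitlines()
    if len(lines) % 4:
        raise ValueError(f"{path}: truncated FASTQ record at line {len(lines)}")
    for i in range(0, len(lines), 4):
        head, seq, plus, qual = lines[i : i + 4]
        if not head.startswith("@"):
            raise ValueError(f"{path}: line {i + 1}: header must start with '@'")
        if not plus.startswith("+"):
            raise ValueError(f"{path}: line {i + 3}: separator must start with '+'")
        if len(seq) != len(qual):
            raise ValueError(f"{path}: line {i + 2}: sequence/quality length mismatch")
        if set(seq.upper()) - set("ACGTN"):
            raise ValueError(f"{path}: line {i + 2}: non-nucleotide characters")
        reads[head[1:].split()[0]] = seq.upper()
    return reads


# ----------------------------------------------------------------------
def run_all(cfg: RunConfig) -> Path:
    """Execute the configured stages in dependency order; returns the run dir."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "manifest.json").write_text(
        json.dumps({"config": cfg.to_dict(), "version": __version__}, indent=1)
    )
    for stage in STAGES:
        if stage not in cfg.stages:
            continue
        func = _STAGE_FUNCS[stage]
        t0 = time.time()
        func(cfg, out)
        log.info("stage %s done in %.1fs", stage, time.time() - t0)
    return out


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"stage '{stage}' needs {path.name}; run its upstream stage first"
        )
    return path


def stage_simulate(cfg: RunConfig, out: Path) -> None:
    d = out / "simulate"
    d.mkdir(exist_ok=True)
    key = _stage_key(cfg, "simulate", [])
    if _cached(d, key):
        log.info("simulate: cached")
        return
    genes = []
    truth_rows = []
    for si in range(cfg.n_species):
        species = f"sp{si + 1}"
        for fi, fam in enumerate(cfg.families):
            model = SpidroinGeneModel.from_family(
                fam, species_seed=cfg.seed * 10007 + si * 101 + fi
            )
            g = generate_gene(model, seed=cfg.seed * 7919 + si * 211 + fi * 17,
                              gene_id=f"{species}_{fam}")
            genes.append(g)
            truth_rows.extend(g.truth_rows())
    write_fasta([(g.gene_id, g.cds) for g in genes], d / "genes.fasta")
    pd.DataFrame(truth_rows, columns=["gene_id", "domain", "start", "end", "n_copies"]).to_csv(
        d / "truth.tsv", sep="\t", index=False
    )
    write_fasta(make_contig_fixtures(genes, "repeat_collapse"), d / "contigs.fasta")
    curate_ids = {
        g.gene_id for g in genes if g.model.family_label in cfg.curate_families
    }
    refs = [(g.gene_id, g.cds) for g in genes if g.gene_id in curate_ids]
    rcfg = ReadSimConfig(
        rng_seed=cfg.seed,
        coverage_short=cfg.coverage_short,
        coverage_long=cfg.coverage_long,
        short_error_rate=cfg.short_error_rate,
        long_error_rate=cfg.long_error_rate,
    )
    r1, r2 = simulate_short_reads(refs, rcfg)
    write_fastq(r1, d / "short_1.fastq")
    write_fastq(r2, d / "short_2.fastq")
    write_fastq(simulate_long_reads(refs, rcfg), d / "long.fastq")
    write_fasta([(g.gene_id, g.protein) for g in genes], d / "proteins.fasta")
    prot_map = {g.gene_id: (g.model.family_label, g.protein) for g in genes
                if g.gene_id.startswith("sp1_")}
    obs = simulate_peptide_observations(
        prot_map, PeptideObservationModel(rng_seed=cfg.seed)
    )
    obs.to_csv(d / "observations.tsv", sep="\t", index=False)
    _mark(d, key)


def stage_curate(cfg: RunConfig, out: Path) -> None:
    d = out / "curate"
    d.mkdir(exist_ok=True)
    sim = out / "simulate"
    inputs = [
        _require(sim / n, "curate")
        for n in ("contigs.fasta", "short_1.fastq", "short_2.fastq", "long.fastq", "genes.fasta")
    ]
    key = _stage_key(cfg, "curate", inputs)
    if _cached(d, key):
        log.info("curate: cached")
        return
    contigs = read_fasta(sim / "contigs.fasta")
    short = read_fastq_strict(sim / "short_1.fastq") | read_fastq_strict(sim / "short_2.fastq")
    long_reads = read_fastq_strict(sim / "long.fastq")
    genes = dict(read_fasta(sim / "genes.fasta"))
    truth = pd.read_csv(sim / "truth.tsv", sep="\t")
    rows = []
    fasta_out = []
    for contig_id, _ in contigs:
        gene_id = contig_id.split("|")[0]
        if gene_id not in genes:
            continue
        fam = gene_id.split("_", 1)[1]
        if fam not in cfg.curate_families:
            continue
        tt = truth[truth.gene_id == gene_id].set_index("domain")
        cds = genes[gene_id]
        ntd = cds[tt.loc["NTD", "start"] : tt.loc["NTD", "end"]]
        ctd = cds[tt.loc["CTD", "start"] : tt.loc["CTD", "end"]]
        profiles = [
            (f"{gene_id}_NTD", "NTD", translate(ntd)),
            (f"{gene_id}_CTD", "CTD", translate(ctd)),
        ]
        g_short = {k: v for k, v in short.items() if k.startswith(gene_id + ":")}
        g_long = {k: v for k, v in long_reads.items() if k.startswith(gene_id + ":")}
        cg = curate_gene(
            [(contig_id, dict(contigs)[contig_id])], g_short, g_long, profiles,
            gene_id=gene_id, family_label=fam,
            k=cfg.k, min_depth=cfg.min_depth, min_purity=cfg.min_purity,
        )
        rows.append({
            "gene_id": cg.gene_id, "family": cg.family_label,
            "ntd_len": len(cg.ntd_nt), "unit_len": len(cg.repeat_unit_nt),
            "ctd_len": len(cg.ctd_nt), "n_copies": cg.n_copies_estimate,
            "continuity": cg.continuity_validated, "confidence": cg.confidence,
        })
        fasta_out += [
            (f"{cg.gene_id}_NTD", cg.ntd_nt),
            (f"{cg.gene_id}_RTD_unit", cg.repeat_unit_nt),
            (f"{cg.gene_id}_CTD", cg.ctd_nt),
        ]
    pd.DataFrame(rows).to_csv(d / "curated.tsv", sep="\t", index=False)
    write_fasta(fasta_out, d / "curated.fasta")
    _mark(d, key)


def stage_annotate(cfg: RunConfig, out: Path) -> None:
    d = out / "annotate"
    d.mkdir(exist_ok=True)
    sim = out / "simulate"
    inputs = [_require(sim / "genes.fasta", "annotate")]
    key = _stage_key(cfg, "annotate", inputs)
    if _cached(d, key):
        log.info("annotate: cached")
        return
    genes = read_fasta(sim / "genes.fasta")
    truth = pd.read_csv(sim / "truth.tsv", sep="\t")
    annotations = []
    for gene_id, cds in genes:
        fam = gene_id.split("_", 1)[1]
        tt = truth[truth.gene_id == gene_id].set_index("domain")
        profiles = [
            (f"{gene_id}_NTD", "NTD", translate(cds[tt.loc["NTD", "start"]: tt.loc["NTD", "end"]])),
            (f"{gene_id}_CTD", "CTD", translate(cds[tt.loc["CTD", "start"]: tt.loc["CTD", "end"]])),
        ]
        annotations.append(segment_domains(cds, profiles, gene_id=gene_id, family=fam))
    catalog_table(annotations).to_csv(d / "catalog.tsv", sep="\t", index=False)
    write_gff3(annotations, d / "domains.gff3")
    (d / "annotations.json").write_text(
        "[\n" + ",\n".join(a.to_json() for a in annotations) + "\n]"
    )
    _mark(d, key)


def stage_compose(cfg: RunConfig, out: Path) -> None:
    d = out / "compose"
    d.mkdir(exist_ok=True)
    sim = out / "simulate"
    inputs = [_require(sim / "genes.fasta", "compose")]
    key = _stage_key(cfg, "compose", inputs)
    if _cached(d, key):
        log.info("compose: cached")
        return
    genes = read_fasta(sim / "genes.fasta")
    truth = pd.read_csv(sim / "truth.tsv", sep="\t")
    rows = []
    for gene_id, cds in genes:
        tt = truth[truth.gene_id == gene_id].set_index("domain")
        rtd_aa = translate(cds[tt.loc["RTD", "start"] : tt.loc["RTD", "end"]])
        rows.append((gene_id, rtd_aa))
    m = CompositionMatrix.from_sequences(rows)
    m.to_frame().to_csv(d / "composition.tsv", sep="\t")
    correlation_matrix(m).to_csv(d / "correlation.tsv", sep="\t")
    res = cluster(m)
    (d / "dendrogram.nwk").write_text(res.newick() + "\n")
    pd.Series(res.flat_groups, name="group").rename_axis("gene_id").to_csv(
        d / "groups.tsv", sep="\t"
    )
    plot_heatmap(m, d / "heatmap.png")
    _mark(d, key)


def stage_phylo(cfg: RunConfig, out: Path) -> None:
    d = out / "phylo"
    d.mkdir(exist_ok=True)
    sim = out / "simulate"
    inputs = [_require(sim / "proteins.fasta", "phylo")]
    key = _stage_key(cfg, "phylo", inputs)
    if _cached(d, key):
        log.info("phylo: cached")
        return
    proteins = read_fasta(sim / "proteins.fasta")
    rows = [(gid, gid.split("_", 1)[1], seq) for gid, seq in proteins]
    terms = trim_terminals(rows, "C")
    msa = align_terminals(terms)
    with open(d / "aligned.fasta", "w") as fh:
        for tid, row in zip(msa.ids, msa.rows):
            fh.write(f">{tid}\n{row}\n")
    tree = bootstrap(msa, reps=cfg.bootstrap_reps, seed=cfg.seed)
    (d / "tree.nwk").write_text(tree.newick() + "\n")
    labels = {r.taxon: r.family for r in terms.records}
    monophyly_report(tree, labels).to_csv(d / "monophyly.tsv", sep="\t", index=False)
    _mark(d, key)


def stage_proteome(cfg: RunConfig, out: Path) -> None:
    d = out / "proteome"
    d.mkdir(exist_ok=True)
    sim = out / "simulate"
    inputs = [_require(sim / n, "proteome") for n in ("proteins.fasta", "observations.tsv")]
    key = _stage_key(cfg, "proteome", inputs)
    if _cached(d, key):
        log.info("proteome: cached")
        return
    obs = pd.read_csv(sim / "observations.tsv", sep="\t")
    proteins = {gid: seq for gid, seq in read_fasta(sim / "proteins.fasta")
                if gid.startswith("sp1_")}
    records, unmatched = match_observations(obs, proteins)
    empai_table(records).to_csv(d / "empai.tsv", sep="\t", index=False)
    report = region_report(records)
    report["empai"].to_csv(d / "empai_by_region.tsv", sep="\t")
    report["ranks"].to_csv(d / "ranks.tsv", sep="\t")
    report["ratios"].to_csv(d / "ratios.tsv", sep="\t", index=False)
    unmatched.to_csv(d / "unmatched.tsv", sep="\t", index=False)
    _mark(d, key)


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "curate": stage_curate,
    "annotate": stage_annotate,
    "compose": stage_compose,
    "phylo": stage_phylo,
    "proteome": stage_proteome,
}
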