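"""In-silico digestion, peptide observability and emPAI quantification.

Web-thread proteomics starts from identified peptide lists: proteins are
digested in silico with the trypsin rule (cleave after K/R, never before
P; a Lys-C pre-digest adds no sites under this convention), peptides are
filtered for observability (carbamidomethyl-Cys fixed, charges 2-3 inside
the m/z 400-1500 scan range), and protein amounts are estimated by emPAI

    emPAI = 10^(n_observed / n_observable) - 1,

the exponentially modified ratio of observed to observable distinct
peptides.  Because counting is by distinct sequence, emPAI is invariant to
how many times a repeat-unit peptide recurs in a protein — a deliberate
property, and a caveat for highly repetitive spidroins, which expose few
distinct peptides relative to their mass fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from pyteomics import mass as ptmass
from scipy import stats

WATER = 18.010565
PROTON = 1.007276
CARBAMIDOMETHYL = 57.02146

_STD = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class Peptide:
    sequence: str
    missed_cleavages: int
    nonstandard: bool = field(default=False, compare=False)

    @property
    def mass(self) -> float | None:
        """Monoisotopic mass with fixed carbamidomethyl-Cys; None when the
        peptide contains non-standard residues."""
        if self.nonstandard:
            return None
        m = sum(ptmass.std_aa_mass[aa] for aa in self.sequence) + WATER
        return m + CARBAMIDOMETHYL * self.sequence.count("C")

    def mz(self, z: int) -> float | None:
        m = self.mass
        return None if m is None else (m + z * PROTON) / z


def cleavage_sites(protein: str) -> list[int]:
    """Positions after which the trypsin rule cuts (after K/R, not before P)."""
    return [
        i + 1
        for i in range(len(protein) - 1)
        if protein[i] in "KR" and protein[i + 1] != "P"
    ]


def digest(protein: str, max_missed: int = 2) -> list[Peptide]:
    """All tryptic peptides with up to ``max_missed`` internal missed sites.

    Peptides containing non-standard residues are emitted flagged and carry
    no mass.  A protein without any cleavage site yields itself as the
    single peptide.
    """
    protein = protein.upper()
    bounds = [0] + cleavage_sites(protein) + [len(protein)]
    out: list[Peptide] = []
    for i in range(len(bounds) - 1):
        for miss in range(max_missed + 1):
            j = i + 1 + miss
            if j >= len(bounds):
                break
            seq = protein[bounds[i] : bounds[j]]
            if not seq:
                continue
            out.append(
                Peptide(seq, miss, nonstandard=bool(set(seq) - _STD))
            )
    return out


def observable_filter(
    peptides: list[Peptide],
    mz_range: tuple[float, float] = (400.0, 1500.0),
    charges: tuple[int, ...] = (2, 3),
) -> set[str]:
    """Distinct peptide sequences with any allowed charge inside the scan range."""
    lo, hi = mz_range
    out = set()
    for p in peptides:
        if p.nonstandard:
            continue
        for z in charges:
            mz = p.mz(z)
            if mz is not None and lo <= mz <= hi:
                out.add(p.sequence)
                break
    return out


def observable_set(
    protein: str,
    mz_range: tuple[float, float] = (400.0, 1500.0),
    charges: tuple[int, ...] = (2, 3),
    include_missed: bool = False,
) -> set[str]:
    """The protein's observable peptides.

    By emPAI convention the denominator uses fully cleaved peptides only;
    ``include_missed`` widens it to missed-cleavage forms.
    """
    peps = digest(protein, max_missed=2 if include_missed else 0)
    return observable_filter(peps, mz_range, charges)


def empai(n_observed: int, n_observable: int) -> float:
    """emPAI = 10^(n_observed/n_observable) - 1, in [0, 9]."""
    if n_observable < 1:
        raise ValueError("n_observable must be >= 1")
    if not 0 <= n_observed <= n_observable:
        raise ValueError("need 0 <= n_observed <= n_observable")
    return 10.0 ** (n_observed / n_observable) - 1.0


@dataclass
class EmPAIRecord:
    protein_id: str
    region: str
    n_observed: int
    n_observable: int
    empai: float


def match_observations(
    observations: pd.DataFrame,
    proteins: dict[str, str],
    mz_range: tuple[float, float] = (400.0, 1500.0),
    charges: tuple[int, ...] = (2, 3),
) -> tuple[list[EmPAIRecord], pd.DataFrame]:
    """Map observed peptides onto proteins and compute per-region emPAI.

    ``observations`` needs columns (region, peptide); counting is by
    distinct peptide sequence against each protein's observable set, so a
    repeat peptide occurring many times in one protein counts once.
    Peptides matching several proteins count for each and are flagged
    shared; peptides matching none are returned in the unmatched table.
    """
    required = {"region", "peptide"}
    if not required <= set(observations.columns):
        raise ValueError(f"observations must have columns {sorted(required)}")
    obs_sets = {pid: observable_set(seq, mz_range, charges) for pid, seq in proteins.items()}
    records: list[EmPAIRecord] = []
    unmatched_rows = []
    shared: set[str] = set()
    for region, group in observations.groupby("region", sort=True):
        peps = set(group["peptide"])
        for pep in sorted(peps):
            owners = [pid for pid, s in obs_sets.items() if pep in s]
            if not owners:
                unmatched_rows.append({"region": region, "peptide": pep})
            elif len(owners) > 1:
                shared.add(pep)
        for pid, s in obs_sets.items():
            if not s:
                continue
            n_obs = len(peps & s)
            records.append(EmPAIRecord(pid, str(region), n_obs, len(s), empai(n_obs, len(s))))
    unmatched = pd.DataFrame(unmatched_rows, columns=["region", "peptide"])
    unmatched.attrs["shared_peptides"] = sorted(shared)
    return records, unmatched


def empai_table(records: list[EmPAIRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "protein_id": r.protein_id,
                "region": r.region,
                "n_observed": r.n_observed,
                "n_observable": r.n_observable,
                "empai": r.empai,
            }
            for r in records
        ]
    )


def region_report(records: list[EmPAIRecord]) -> dict[str, pd.DataFrame]:
    """Region comparison: emPAI matrix, within-region ranks, region ratios.

    When several records exist per (protein, region) — replicate runs —
    emPAI values are averaged for the matrix and compared across regions by
    a Wilcoxon rank-sum test per protein and region pair.
    """
    df = empai_table(records)
    if df.empty:
        raise ValueError("no emPAI records")
    matrix = df.pivot_table(index="protein_id", columns="region", values="empai", aggfunc="mean")
    ranks = matrix.rank(axis=0, ascending=False, method="min")
    regions = list(matrix.columns)
    ratio_rows = []
    for i, a in enumerate(regions):
        for b in regions[i + 1 :]:
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = matrix[a] / matrix[b]
            ratio_rows.append(pd.DataFrame({"protein_id": matrix.index, "region_a": a,
                                            "region_b": b, "ratio": ratio.to_numpy()}))
    ratios = pd.concat(ratio_rows, ignore_index=True) if ratio_rows else pd.DataFrame()
    tests = []
    counts = df.groupby(["protein_id", "region"]).size()
    if (counts > 1).any():
        for pid, sub in df.groupby("protein_id"):
            for i, a in enumerate(regions):
                for b in regions[i + 1 :]:
                    xa = sub.loc[sub["region"] == a, "empai"]
                    xb = sub.loc[sub["region"] == b, "empai"]
                    if len(xa) > 1 and len(xb) > 1:
                        stat, p = stats.ranksums(xa, xb)
                        tests.append({"protein_id": pid, "region_a": a, "region_b": b,
                                      "statistic": stat, "pvalue": p})
    return {
        "empai": matrix,
        "ranks": ranks,
        "ratios": ratios,
        "tests": pd.DataFrame(tests),
    }
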