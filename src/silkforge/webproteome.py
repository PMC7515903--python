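"""Simulated web-region peptide observations.

Emulates mass-spectrometry surveys of orb-web parts: each web region
(whole web, radius+spiral area, stabilimentum) carries its own relative
protein abundances — aciniform silk dominating the stabilimentum, the
capture-thread proteins the radius/spiral area — and peptide detection is
a Bernoulli event per observable peptide whose probability saturates with
abundance.  Only peptides that the proteomics module's digestion and
observability rules produce can ever be emitted, so simulated TSVs are
always consistent with the matcher they feed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .proteomics import observable_set

REGIONS = ("whole_web", "radius_spiral", "stabilimentum")

#: region-biased relative abundances by spidroin family: stabilimentum is
#: essentially aciniform silk, the radius/spiral area is dominated by the
#: dragline plus the cribellate capture-thread proteins.
DEFAULT_ABUNDANCES: dict[str, dict[str, float]] = {
    "whole_web": {
        "MaSp": 10.0, "MiSp": 5.0, "CrSp": 4.0, "Pflag": 4.0,
        "AcSp": 3.0, "CySp": 0.5, "PySp": 1.0, "Flag": 0.0, "AgSp": 0.0,
    },
    "radius_spiral": {
        "MaSp": 12.0, "MiSp": 6.0, "CrSp": 8.0, "Pflag": 6.0,
        "AcSp": 1.0, "CySp": 0.2, "PySp": 1.0, "Flag": 0.0, "AgSp": 0.0,
    },
    "stabilimentum": {
        "MaSp": 1.5, "MiSp": 0.8, "CrSp": 0.8, "Pflag": 0.8,
        "AcSp": 10.0, "CySp": 0.5, "PySp": 0.5, "Flag": 0.0, "AgSp": 0.0,
    },
}


@dataclass
class PeptideObservationModel:
    """Detection model: p(detect) = p_max * a / (a + k), monotone in a."""

    abundances: dict[str, dict[str, float]] = field(
        default_factory=lambda: {r: dict(v) for r, v in DEFAULT_ABUNDANCES.items()}
    )
    p_max: float = 0.9
    half_saturation: float = 2.0
    count_scale: float = 1.0
    rng_seed: int = 0

    def detection_probability(self, abundance: float) -> float:
        if abundance <= 0:
            return 0.0
        p = self.p_max * abundance / (abundance + self.half_saturation)
        return float(min(max(p, 0.0), 1.0))


def simulate_peptide_observations(
    proteins: dict[str, tuple[str, str]],
    model: PeptideObservationModel,
) -> pd.DataFrame:
    """Simulated peptide identifications per web region.

    ``proteins`` maps protein id -> (family_label, aa_sequence).  For each
    region, each observable peptide of each protein is detected with the
    model's saturating probability at that protein's regional abundance;
    detected peptides get a spectral count 1 + Poisson(scale * p).
    Returns a tidy frame (region, protein, peptide, count).
    """
    rng = np.random.default_rng(model.rng_seed)
    rows = []
    for region in model.abundances:
        region_ab = model.abundances[region]
        for pid in sorted(proteins):
            family, seq = proteins[pid]
            a = region_ab.get(family, region_ab.get(pid, 0.0))
            p = model.detection_probability(a)
            if p == 0.0:
                continue
            for pep in sorted(observable_set(seq)):
                if rng.random() < p:
                    count = 1 + rng.poisson(model.count_scale * p)
                    rows.append(
                        {"region": region, "protein": pid, "peptide": pep, "count": int(count)}
                    )
    return pd.DataFrame(rows, columns=["region", "protein", "peptide", "count"])


def write_observations_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)
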