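import numpy as np
import pytest

from metaqtl.compendium import QTLRecord
from metaqtl.map_projection import GeneticMap
from metaqtl.meta_analysis import ChromosomeQTLSet, QTLObservation


@pytest.fixture
def simple_record():
    return QTLRecord(
        qtl_id="q1", study_ref="S01", trait="PH", chromosome=1,
        source_map_id="S01", position=50.0, population_type="F2",
        population_size=200, ci_lo=40.0, ci_hi=60.0, lod=4.0, pve_percent=10.0,
    )


@pytest.fixture
def identity_maps():
    """A source map identical to the reference."""
    chroms = {1: (("A", 0.0), ("B", 10.0), ("C", 20.0), ("D", 30.0))}
    return (
        GeneticMap("src", chroms),
        GeneticMap("ref", chroms),
    )


def make_qset(rng: np.random.Generator, loci, n_per, sigma_range=(3.0, 8.0), chromosome=1):
    """Gaussian observations around each locus with per-QTL known sigma."""
    items = []
    for li, locus in enumerate(loci):
        for i in range(n_per):
            s = float(rng.uniform(*sigma_range))
            items.append(QTLObservation(
                qtl_id=f"q{li}_{i}", x=float(rng.normal(locus, s)), sigma=s,
                trait="PH" if rng.random() < 0.5 else "EH",
            ))
    return ChromosomeQTLSet(chromosome=chromosome, items=tuple(items))
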