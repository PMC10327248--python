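import numpy as np
import pytest

from afmfit.afm_topography import TipModel
from afmfit.io_formats import AFMSurface, Bead, CoarseModel, EnergyRecord
from afmfit.synthetic_fixtures import SyntheticSpec, build_toy_rna

# minimal full-atom PDB: three RNA residues (G, A, C) with enough atoms to
# coarse-grain (P, C4', base ring atoms); coordinates are arbitrary but fixed
TOY_PDB = """\
ATOM      1  O5'   G A   1      10.000  10.000  10.000  1.00  0.00
ATOM      2  C4'   G A   1      11.000  10.500  10.200  1.00  0.00
ATOM      3  N9    G A   1      12.500  11.000  10.800  1.00  0.00
ATOM      4  C8    G A   1      13.300  10.400  11.500  1.00  0.00
ATOM      5  N7    G A   1      14.400  11.000  11.900  1.00  0.00
ATOM      6  C5    G A   1      14.300  12.200  11.300  1.00  0.00
ATOM      7  C6    G A   1      15.100  13.300  11.300  1.00  0.00
ATOM      8  N1    G A   1      14.700  14.300  10.500  1.00  0.00
ATOM      9  C2    G A   1      13.600  14.300   9.800  1.00  0.00
ATOM     10  N3    G A   1      12.800  13.300   9.800  1.00  0.00
ATOM     11  C4    G A   1      13.200  12.300  10.500  1.00  0.00
ATOM     12  P     A A   2      16.000  10.000  12.000  1.00  0.00
ATOM     13  C4'   A A   2      17.200  10.800  12.500  1.00  0.00
ATOM     14  N9    A A   2      18.500  11.200  13.000  1.00  0.00
ATOM     15  C8    A A   2      19.200  10.600  14.000  1.00  0.00
ATOM     16  N7    A A   2      20.300  11.200  14.300  1.00  0.00
ATOM     17  C5    A A   2      20.300  12.300  13.500  1.00  0.00
ATOM     18  C6    A A   2      21.200  13.300  13.300  1.00  0.00
ATOM     19  N1    A A   2      20.900  14.200  12.300  1.00  0.00
ATOM     20  C2    A A   2      19.800  14.100  11.600  1.00  0.00
ATOM     21  N3    A A   2      18.900  13.200  11.700  1.00  0.00
ATOM     22  C4    A A   2      19.200  12.300  12.700  1.00  0.00
ATOM     23  P     C A   3      22.000  10.000  15.000  1.00  0.00
ATOM     24  C4'   C A   3      23.100  10.900  15.400  1.00  0.00
ATOM     25  N1    C A   3      24.400  11.200  16.000  1.00  0.00
ATOM     26  C2    C A   3      25.300  10.300  16.500  1.00  0.00
ATOM     27  N3    C A   3      26.400  10.700  17.100  1.00  0.00
ATOM     28  C4    C A   3      26.700  12.000  17.200  1.00  0.00
ATOM     29  C5    C A   3      25.800  12.900  16.700  1.00  0.00
ATOM     30  C6    C A   3      24.700  12.500  16.100  1.00  0.00
END
"""


@pytest.fixture
def toy_pdb(tmp_path):
    p = tmp_path / "toy.pdb"
    p.write_text(TOY_PDB)
    return p


@pytest.fixture(scope="session")
def hairpin():
    """20-residue toy hairpin (59 beads) with its secondary structure."""
    return build_toy_rna(SyntheticSpec(n_residues=20, seed=0))


@pytest.fixture(scope="session")
def tip():
    return TipModel()


def simple_model(coords, kinds=None, residues=None, nts=None):
    """CoarseModel from raw coordinates; defaults to one sugar+base pair
    per two beads laid out as full residues of three beads."""
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    beads = []
    if kinds is None:
        # pack into residues of 3 beads: phosphate, sugar, base
        kinds, residues = [], []
        for i in range(n):
            r, k = divmod(i, 3)
            kinds.append(("phosphate", "sugar", "base")[k])
            residues.append(r + 1)
        # a trailing partial residue would violate the invariant
        assert n % 3 == 0, "simple_model default layout needs len % 3 == 0"
    nts = nts or ["A"] * n
    for c, k, r, nt in zip(coords, kinds, residues, nts):
        beads.append(Bead(r, k, c, nt))
    return CoarseModel(beads)


def make_records(values):
    """EnergyRecords from a dict of per-field arrays (missing fields 0)."""
    from afmfit.io_formats import ENERGY_FIELDS

    n = len(next(iter(values.values())))
    recs = []
    for i in range(n):
        kw = {f: 0.0 for f in ENERGY_FIELDS}
        for k, v in values.items():
            kw[k] = float(v[i])
        recs.append(EnergyRecord(frame=i + 1, **kw))
    return recs


@pytest.fixture
def flat_surface():
    return AFMSurface(np.zeros((8, 8)) + 1.0, pixel_size=5.0)
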