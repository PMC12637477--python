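import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from chronotime import SimConfig, SpatialSection

MINIMAL_PANEL = [
    ("Lyz2", "marker:myeloid"),
    ("Cd3e", "marker:T"),
    ("Cxcl9", "chemokine"),
    ("Ifng", "effector"),
    ("Actb", "background"),
]


@pytest.fixture
def small_config():
    """Small, fast section: all four types, full default panel."""
    return SimConfig(n_tumor=80, n_myeloid=60, n_t=50, n_other=30)


@pytest.fixture
def minimal_config():
    """Immune cells only with a 5-gene panel, for speed-critical tests."""
    return SimConfig(
        n_tumor=0, n_myeloid=60, n_t=50, n_other=0, gene_panel=MINIMAL_PANEL
    )


def make_section(
    coords,
    types,
    counts=None,
    gene_names=None,
    section_id="s1",
    condition="ZT2",
):
    """Hand-built section from explicit coordinates and type labels."""
    coords = np.asarray(coords, float)
    n = len(coords)
    if gene_names is None:
        gene_names = ["G1"]
    if counts is None:
        counts = np.zeros((len(gene_names), n), dtype=int)
    return SpatialSection(
        section_id=section_id,
        condition=condition,
        cells=pd.DataFrame(
            {
                "cell_id": [f"{section_id}_c{i}" for i in range(n)],
                "x_um": coords[:, 0],
                "y_um": coords[:, 1],
                "cell_type": list(types),
            }
        ),
        counts=sp.csr_matrix(np.asarray(counts)),
        gene_names=list(gene_names),
    )


def random_section(rng, n_cells, types=("T", "myeloid", "tumor"),
                   section_id="s1", condition="ZT2", width=1000.0):
    """Random coordinates and labels, no expression structure."""
    coords = rng.uniform(0, width, size=(n_cells, 2))
    labels = rng.choice(types, size=n_cells)
    return make_section(coords, labels, section_id=section_id,
                        condition=condition)
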