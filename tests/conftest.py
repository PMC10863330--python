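import numpy as np
import pytest

from fielddose import conductor, mep, phantom, solver
from fielddose.conductor import ConductivityTable, VoxelConductorModel


@pytest.fixture(scope="session")
def small_phantom():
    """Coarse default-shell sphere phantom (3 mm grid) for cheap tests."""
    return phantom.make_sphere_phantom(85.0, phantom.DEFAULT_SHELLS, 3.0)


@pytest.fixture(scope="session")
def plate_model():
    """Homogeneous cube with full opposite-face Dirichlet plates."""
    n = 6
    model = VoxelConductorModel(
        sigma_elem=np.full((n, n, n), 0.2),
        labels_elem=np.full((n, n, n), phantom.TISSUE_CODES["gray_matter"], np.int16),
        spacing_mm=(2.0, 2.0, 2.0),
        origin_mm=(0.0, 0.0, 0.0),
    )
    ns = model.node_shape
    jj, kk = np.meshgrid(np.arange(ns[1]), np.arange(ns[2]), indexing="ij")
    model.dirichlet_nodes["anode"] = np.unique(model.node_index(np.zeros_like(jj), jj, kk))
    model.dirichlet_nodes["cathode"] = np.unique(
        model.node_index(np.full_like(jj, ns[0] - 1), jj, kk)
    )
    return model


@pytest.fixture(scope="session")
def sphere_solution():
    """Full-stack sphere phantom with the default montage, solved at 1 mA.

    Shared by the conservation, metrics and acceptance tests; 2 mm grid.
    """
    from fielddose.experiments import default_montage

    shells = phantom.DEFAULT_SHELLS
    vol = phantom.make_sphere_phantom(85.0, shells, 2.0)
    geom = phantom.sphere_geometry(85.0, shells)
    tab = ConductivityTable.default()
    model = conductor.assign_conductivities(vol, tab, 2, geometry=geom)
    for spec in default_montage(vol):
        model = conductor.place_electrode(model, spec, tab, 2)
    sol = solver.solve_tdcs(model, 1.0e-3)
    return vol, model, sol


@pytest.fixture(scope="session")
def mep_dataset():
    """Default-truth synthetic MEP experiment (21 participants)."""
    return mep.generate_dataset(mep.StudyDesign(), mep.TruthParams(seed=42))


@pytest.fixture(scope="session")
def lean_field_fit(mep_dataset):
    """Lean field-family mixed-model fit on the shared dataset."""
    from fielddose import dose

    df, prep = dose.prepare_analysis_table(mep_dataset, "field_nmep")
    spec = dose.build_spec("field_nmep", lean=True)
    return dose.fit_lmm(spec, df, prep, screen_outliers=False)
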