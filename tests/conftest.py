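"""Shared fixtures: small verification meshes and one session-scoped solved tibia.

The synthetic-tibia study (phantom -> segmentation -> VOIs -> FE solve ->
strain summaries) is by far the most expensive fixture, so it is solved once
per session and shared by every test that needs a realistic strain field.
"""

from __future__ import annotations

import numpy as np
import pytest

from osteoadapt.microfe import (
    apply_axial_compression,
    assign_materials,
    solve_linear_elasticity,
    voxel_mesh,
)
from osteoadapt.phantoms import PhantomSpec, make_synthetic_tibia
from osteoadapt.strainstats import strain_field_from_solution, voi_strain_summary
from osteoadapt.volumes import VOISpec, extract_voi, segment

#: Reduced-scale study phantom: 1.2 mm straight tibia at the 10 um scan
#: resolution, hollow diaphysis + flared trabecular metaphysis.
STUDY_SPEC = PhantomSpec(seed=3)

#: Much smaller phantom for fast end-to-end pipeline tests.
MINI_SPEC = PhantomSpec(
    total_length=0.6,
    diaphysis_outer_radius=0.12,
    diaphysis_inner_radius=0.08,
    metaphysis_outer_radius=0.15,
    metaphysis_shell_thickness=0.03,
    metaphysis_length_fraction=0.32,
    trabecular_feature_size=0.03,
    seed=5,
)

LOADS = (-3.5, -5.2, -7.0)


@pytest.fixture(scope="session")
def tibia_study():
    """Solved axial-compression study on the reduced synthetic tibia.

    One FE solve at the low load (-3.5 N); higher loads follow by linearity.
    Returns a dict with the volume, masks, VOIs, mesh, strain field, and
    per-VOI summaries at -3.5 N.
    """
    vol, gp = make_synthetic_tibia(STUDY_SPEC)
    cort = segment(vol, 0.34, "cortical")
    canc = segment(vol, 0.41, "cancellous")
    mid_voi = extract_voi(cort, VOISpec.midshaft())
    canc_voi = extract_voi(canc, VOISpec.proximal_cancellous(), gp)
    cc_voi = extract_voi(canc, VOISpec.proximal_cortico_cancellous(), gp)
    mesh = voxel_mesh(cort)
    mats = assign_materials(vol, mesh, model="homogeneous", e0=17000.0, nu=0.3)
    lc = apply_axial_compression(mesh, LOADS[0])
    disp = solve_linear_elasticity(mesh, mats, lc, rel_tol=1e-6, max_iter=40000)
    field = strain_field_from_solution(mesh, disp)
    summaries = {
        name: voi_strain_summary(field, voi, mesh, LOADS[0], name=name)
        for name, voi in (
            ("midshaft_cortical", mid_voi),
            ("proximal_cancellous", canc_voi),
            ("proximal_cortico_cancellous", cc_voi),
        )
    }
    return {
        "volume": vol,
        "growth_plate_slice": gp,
        "cortical_mask": cort,
        "cancellous_mask": canc,
        "vois": {"midshaft_cortical": mid_voi, "proximal_cancellous": canc_voi,
                 "proximal_cortico_cancellous": cc_voi},
        "mesh": mesh,
        "materials": mats,
        "loadcase": lc,
        "displacement": disp,
        "field": field,
        "summaries": summaries,
    }


@pytest.fixture(scope="session")
def solved_bar():
    """Solid-cylinder bar under axial compression (nu = 0): closed-form F/(AE)."""
    from osteoadapt.phantoms import make_tube_phantom

    vol = make_tube_phantom(0.15, 0.0, 0.4, density=1.0, voxel_size=10.0)
    mask = segment(vol, 0.34)
    mesh = voxel_mesh(mask)
    mats = assign_materials(None, mesh, e0=17000.0, nu=0.0)
    lc = apply_axial_compression(mesh, -3.5)
    disp = solve_linear_elasticity(mesh, mats, lc, rel_tol=1e-8)
    return {"volume": vol, "mask": mask, "mesh": mesh, "materials": mats,
            "loadcase": lc, "displacement": disp}
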