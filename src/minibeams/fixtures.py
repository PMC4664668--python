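"""The five canonical study configurations, regenerable byte-for-byte.

These encode the printed parameters of the underlying experimental and
simulation studies: the 109-MeV proton pencil minibeam film measurement,
the 10-cm-range planar proton and Li-7 arrays (1.0-mm on-center) whose
merge depths anchor the broadening model, a 10-cm-range He-4 pencil
array as the pencil-lattice representative, and the four-directional
interleaved carbon minibeam rabbit-study plan (0.3 mm, 1.05-mm
on-center, SOBP over a 6.5-mm target proximal at 36 mm, 14-Gy pedestal,
RBE 3.0).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .config import BeamConfig, ModelConfig, PhantomConfig, PlanConfig, RunConfig, save_config

__all__ = ["Fixture", "FIXTURES", "build_fixture", "generate_fixtures"]


@dataclass(frozen=True)
class Fixture:
    name: str
    config: RunConfig
    provenance: str


def _proton_pencil_109() -> Fixture:
    return Fixture(
        name="proton_pencil_109",
        config=RunConfig(
            beam=BeamConfig(
                species="proton",
                energy_mev_u=109.0,
                shape="pencil",
                incident_width_fwhm_mm=0.3,
                spacing_on_center_mm=1.0,
            ),
            phantom=PhantomConfig(depth_mm=85.0),
        ),
        provenance="109-MeV proton pencil minibeams, 0.3-mm pinhole collimator, "
        "1.0-mm on-center pattern; radiochromic-film broadening measurement geometry",
    )


def _planar_10cm(species: str) -> Fixture:
    return Fixture(
        name=f"{species}_planar_10cm",
        config=RunConfig(
            beam=BeamConfig(
                species=species,
                range_cm=10.0,
                shape="planar",
                incident_width_fwhm_mm=0.3,
                spacing_on_center_mm=1.0,
            ),
            phantom=PhantomConfig(depth_mm=95.0),
        ),
        provenance=f"0.3-mm planar {species} minibeams spaced 1.0-mm on-center at the "
        "incident energy giving 10-cm range in water; merge-depth simulation geometry",
    )


def _he4_pencil_10cm() -> Fixture:
    return Fixture(
        name="he4_pencil_10cm",
        config=RunConfig(
            beam=BeamConfig(
                species="he4",
                range_cm=10.0,
                shape="pencil",
                incident_width_fwhm_mm=0.3,
                spacing_on_center_mm=0.7,
            ),
            phantom=PhantomConfig(depth_mm=95.0),
        ),
        provenance="0.3-mm He-4 pencil minibeams on a 0.7-mm square lattice, 10-cm "
        "range; pencil-array broadening geometry",
    )


def _carbon_interleave_rabbit() -> Fixture:
    return Fixture(
        name="carbon_interleave_rabbit",
        config=RunConfig(
            beam=BeamConfig(
                species="c12",
                range_cm=4.25,
                shape="planar",
                incident_width_fwhm_mm=0.3,
                spacing_on_center_mm=1.05,
            ),
            phantom=PhantomConfig(depth_mm=40.0),
            plan=PlanConfig(
                target_x_min_mm=36.0,
                target_x_max_mm=42.5,
                target_v_min_mm=-3.25,
                target_v_max_mm=3.25,
                directions=["+x", "+y", "-x", "-y"],
                pedestal_dose_gy=14.0,
                pedestal_to_sobp_ratio=20.0 / 14.0,
                rbe=3.0,
            ),
            model=ModelConfig(),
        ),
        provenance="four-directional interleaved carbon minibeams: 0.3-mm planar "
        "beams, 1.05-mm on-center, 124-135 MeV/u SOBP over a 6.5-mm target with "
        "proximal edge 36-mm deep; 14-Gy pedestal -> 40 Gy / 120 GyE at the target",
    )


_BUILDERS = {
    "proton_pencil_109": _proton_pencil_109,
    "proton_planar_10cm": lambda: _planar_10cm("proton"),
    "li7_planar_10cm": lambda: _planar_10cm("li7"),
    "he4_pencil_10cm": _he4_pencil_10cm,
    "carbon_interleave_rabbit": _carbon_interleave_rabbit,
}

FIXTURES = tuple(_BUILDERS)


def build_fixture(name: str) -> Fixture:
    try:
        return _BUILDERS[name]()
    except KeyError:
        raise KeyError(f"unknown fixture {name!r}; available: {list(FIXTURES)}") from None


def generate_fixtures(outdir) -> list[Fixture]:
    """Write the five canonical configs to ``outdir``; deterministic."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fixtures = [build_fixture(name) for name in FIXTURES]
    for fx in fixtures:
        save_config(fx.config, outdir / f"{fx.name}.yaml", header=fx.provenance)
    return fixtures
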