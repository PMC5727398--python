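"""End-to-end pipeline: generate condition mixtures, measure, summarize.

A run configuration describes polymerization "conditions", each a mixture
of PF numbers with a PF skew; the pipeline generates one synthetic MT per
entry, runs the measurement operators on the rendered data and tabulates
the calls per condition - the workflow behind per-condition architecture
tables.  Everything is deterministic given the seed: per-MT seeds are
spawned from the run seed, so outputs are byte-identical across runs.
"""

from __future__ import annotations

import configparser
import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .lattice import LatticeSpec
from .measure import (
    ArchitectureCall,
    ConditionSummary,
    classify_pf_number,
    measure_axial_repeat,
    measure_moire,
    summarize,
)
from .synth import build_lattice, decorate, render, transverse_sections

__all__ = ["ConditionConfig", "RunConfig", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class ConditionConfig:
    """One polymerization condition: a PF-number mixture at a given skew."""

    name: str
    mix: dict[int, int]  # pf_number -> MT count
    skew_deg: float = -0.4
    monomer_rise: float = 4.15


@dataclass
class RunConfig:
    """Full pipeline configuration (flat key-value file with sections)."""

    conditions: list[ConditionConfig] = field(default_factory=list)
    seed: int = 0
    pixel_nm: float = 0.35
    snr: float = math.inf
    volume_length_nm: float = 70.0
    decorated: bool = True
    measure_moire: bool = False
    moire_length_nm: float = 800.0
    measure_axial: bool = False
    axial_repeats: int = 40
    n_groups: int = 3
    section_thickness_nm: float = 4.0

    def __post_init__(self) -> None:
        for name in ("pixel_nm", "volume_length_nm", "moire_length_nm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_ini(cls, text: str) -> "RunConfig":
        """Parse a config file: a [run] section plus [condition:NAME] sections.

        Example::

            [run]
            seed = 1
            snr = inf
            [condition:GTP]
            mix = 12:2, 13:21, 14:2
            skew_deg = -0.5
        """
        parser = configparser.ConfigParser()
        parser.read_string(text)
        kwargs: dict = {}
        if parser.has_section("run"):
            run = parser["run"]
            for key, cast in [
                ("seed", int),
                ("pixel_nm", float),
                ("snr", float),
                ("volume_length_nm", float),
                ("moire_length_nm", float),
                ("axial_repeats", int),
                ("n_groups", int),
                ("section_thickness_nm", float),
            ]:
                if key in run:
                    kwargs[key] = cast(run[key])
            for key in ("decorated", "measure_moire", "measure_axial"):
                if key in run:
                    kwargs[key] = run.getboolean(key)
        conditions = []
        for section in parser.sections():
            if not section.startswith("condition:"):
                continue
            sec = parser[section]
            if "mix" not in sec:
                raise ValueError(f"[{section}] lacks a 'mix' entry")
            mix = {}
            for token in sec["mix"].split(","):
                n, count = token.split(":")
                mix[int(n)] = int(count)
            conditions.append(
                ConditionConfig(
                    name=section.split(":", 1)[1],
                    mix=mix,
                    skew_deg=float(sec.get("skew_deg", -0.4)),
                    monomer_rise=float(sec.get("monomer_rise", 4.15)),
                )
            )
        return cls(conditions=conditions, **kwargs)


def _analyze_one(
    spec: LatticeSpec, config: RunConfig, seed: int
) -> ArchitectureCall:
    lat = build_lattice(spec, config.volume_length_nm)
    if config.decorated:
        lat = decorate(lat)
    snr = config.snr
    vol = render(
        lat, pixel_nm=config.pixel_nm, mode="volume", snr=snr,
        seed=None if math.isinf(snr) else seed,
    )
    sections = transverse_sections(
        vol, config.section_thickness_nm, config.section_thickness_nm
    )
    n_pf, conf = classify_pf_number(sections)
    call = ArchitectureCall(pf_number=n_pf, pf_confidence=conf)
    if config.measure_moire:
        lat_m = build_lattice(spec, config.moire_length_nm)
        proj = render(
            lat_m, pixel_nm=config.pixel_nm, snr=snr,
            seed=None if math.isinf(snr) else seed + 1,
        )
        call.moire_nm = measure_moire(proj)
    if config.measure_axial:
        lat_a = decorate(
            build_lattice(spec, config.axial_repeats * spec.dimer_repeat)
        )
        proj = render(
            lat_a, pixel_nm=config.pixel_nm, snr=snr,
            seed=None if math.isinf(snr) else seed + 2,
        )
        call.axial_repeat_nm = measure_axial_repeat(proj)
    return call


def run_pipeline(
    config: RunConfig,
) -> tuple[ConditionSummary, list[tuple[str, ArchitectureCall]]]:
    """Generate, measure and summarize every MT of every condition."""
    if not config.conditions:
        raise ValueError("config defines no conditions")
    rng_root = np.random.SeedSequence(config.seed)
    calls: list[tuple[str, ArchitectureCall]] = []
    for cond in config.conditions:
        for n_pf, count in sorted(cond.mix.items()):
            for k in range(count):
                seed = int(rng_root.spawn(1)[0].generate_state(1)[0] % (2**31))
                spec = LatticeSpec(
                    n_pf=n_pf,
                    skew_deg=cond.skew_deg,
                    monomer_rise=cond.monomer_rise,
                    lateral_rise=3 * cond.monomer_rise / 13,
                )
                logger.info(
                    "condition %s: MT %d/%d with %d PFs", cond.name, k + 1,
                    count, n_pf,
                )
                calls.append((cond.name, _analyze_one(spec, config, seed)))
    return summarize(calls, n_groups=config.n_groups), calls
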