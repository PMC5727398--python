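"""Surface-lattice accommodation geometry of the microtubule wall.

A microtubule (MT) is a tube of N protofilaments (PFs), each a head-to-tail
stack of alpha/beta-tubulin heterodimers.  Laterally adjacent PFs are offset
axially by a fixed "lateral rise" set by the tubulin-tubulin interface, so the
monomers trace an S-start helix around the tube ("13_3" = 13 PFs, 3-start,
counted in monomers).  For most (N, S) the intrinsic lateral rise does not
close the cylinder exactly; the residual mismatch is absorbed by tilting the
PFs about the MT axis ("PF skew" or supertwist).  This module implements the
closed-form accommodation relations among

    N   number of protofilaments
    S   monomer helix-start number
    a   monomer rise along the PF (nm)
    d   heterodimer repeat, d = 2a (nm)
    w   lateral centre-to-centre PF spacing (nm)
    dx  intrinsic axial offset per lateral neighbour step (nm)
    th  signed PF skew angle (degrees; negative = left-handed supertwist)
    R   PF centre-line radius, R = N*w / (2*pi)
    L   projected moire repeat, L = w / tan|th|

The moire repeat is the axial period of the fringe pattern produced when the
near and far walls of a skewed MT superpose in 2D projection; it diverges as
the PFs straighten.  The canonical mammalian 13_3 lattice is exactly unskewed
with the default dx = 3a/13.

Sign convention: negative skew = left-handed supertwist (azimuth decreases
with increasing axial coordinate), the convention in which 14_3 MTs
accommodate to roughly -0.76 deg.  Used consistently by the generator and the
measurement operators.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

__all__ = [
    "UNBOUNDED",
    "LatticeSpec",
    "radius_from_pf",
    "skew_from_accommodation",
    "moire_from_skew",
    "skew_from_moire",
    "seam_count",
]

#: Sentinel moire repeat for straight (unskewed) protofilaments.
UNBOUNDED = math.inf

_DEFAULT_MONOMER_RISE = 4.15  # nm
_DEFAULT_INTER_PF = 5.15  # nm
_DEFAULT_LATERAL_RISE = 3.0 * _DEFAULT_MONOMER_RISE / 13.0  # unskewed 13_3


def radius_from_pf(n_pf: int, inter_pf_spacing: float) -> float:
    """PF centre-line radius (nm) from circumference closure.

    N protofilaments at lateral centre-to-centre spacing ``w`` must wrap a
    circle of circumference ``N*w``, hence ``R = N*w / (2*pi)``.
    """
    if n_pf < 3:
        raise ValueError(f"n_pf must be >= 3, got {n_pf}")
    if inter_pf_spacing <= 0:
        raise ValueError(f"inter_pf_spacing must be > 0, got {inter_pf_spacing}")
    return n_pf * inter_pf_spacing / (2.0 * math.pi)


@dataclass(frozen=True)
class LatticeSpec:
    """Geometric parameters of an idealized MT surface lattice.

    ``seam_interfaces`` lists the lateral interfaces (index ``j`` is the
    interface between PF ``j`` and PF ``(j+1) % N``) that are A-lattice,
    i.e. where unlike monomers (alpha-beta) are lateral neighbours.  ``None``
    selects the canonical default: one seam (at the wrap interface) for odd
    start numbers, none for even.  The number of seams must have the parity
    of the start number so the alternating monomer types close around the
    ring.

    ``skew_deg`` is free, not forced to the accommodation value: measured
    lattices (e.g. GMPCPP-grown 12-PF MTs) can exceed the accommodation
    baseline, and that is data, not an error.
    """

    n_pf: int = 13
    start: int = 3
    monomer_rise: float = _DEFAULT_MONOMER_RISE
    inter_pf_spacing: float = _DEFAULT_INTER_PF
    lateral_rise: float = _DEFAULT_LATERAL_RISE
    skew_deg: float = 0.0
    seam_interfaces: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_pf < 3:
            raise ValueError(f"n_pf must be >= 3, got {self.n_pf}")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        for name in ("monomer_rise", "inter_pf_spacing"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.seam_interfaces is None:
            default = (self.n_pf - 1,) if self.start % 2 else ()
            object.__setattr__(self, "seam_interfaces", default)
        else:
            seams = tuple(sorted(set(int(j) for j in self.seam_interfaces)))
            object.__setattr__(self, "seam_interfaces", seams)
            if any(j < 0 or j >= self.n_pf for j in seams):
                raise ValueError(
                    f"seam interface indices must lie in 0..{self.n_pf - 1}: {seams}"
                )
            if len(seams) % 2 != self.start % 2:
                raise ValueError(
                    f"{len(seams)} seam(s) incompatible with start {self.start}: "
                    "the count of A-lattice interfaces must have the parity of "
                    "the start number for monomer types to close around the ring"
                )

    # -- derived quantities -------------------------------------------------

    @property
    def dimer_repeat(self) -> float:
        """Heterodimer repeat d = 2a (nm)."""
        return 2.0 * self.monomer_rise

    @property
    def radius(self) -> float:
        """PF centre-line radius R = N*w/(2*pi) (nm)."""
        return radius_from_pf(self.n_pf, self.inter_pf_spacing)

    # -- constructors -------------------------------------------------------

    @classmethod
    def accommodated(cls, n_pf: int = 13, start: int = 3, **kwargs) -> "LatticeSpec":
        """Spec with the skew set to the lattice-accommodation value."""
        base = cls(n_pf=n_pf, start=start, **kwargs)
        return replace(base, skew_deg=skew_from_accommodation(base))

    @classmethod
    def all_a(cls, n_pf: int = 13, start: int = 3, **kwargs) -> "LatticeSpec":
        """Entirely A-lattice tube: every lateral interface is a seam."""
        return cls(
            n_pf=n_pf, start=start, seam_interfaces=tuple(range(n_pf)), **kwargs
        )

    # -- flat key-value serialization ----------------------------------------

    def to_config(self) -> str:
        lines = [
            f"n_pf = {self.n_pf}",
            f"start = {self.start}",
            f"monomer_rise = {self.monomer_rise!r}",
            f"inter_pf_spacing = {self.inter_pf_spacing!r}",
            f"lateral_rise = {self.lateral_rise!r}",
            f"skew_deg = {self.skew_deg!r}",
            "seam_interfaces = " + ",".join(str(j) for j in self.seam_interfaces),
        ]
        return "\n".join(lines) + "\n"

    @classmethod
    def from_config(cls, text: str) -> "LatticeSpec":
        kv: dict[str, str] = {}
        for raw in text.splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"malformed config line: {raw!r}")
            key, val = (s.strip() for s in line.split("=", 1))
            kv[key] = val
        kwargs: dict = {}
        for key in ("n_pf", "start"):
            if key in kv:
                kwargs[key] = int(kv[key])
        for key in ("monomer_rise", "inter_pf_spacing", "lateral_rise", "skew_deg"):
            if key in kv:
                kwargs[key] = float(kv[key])
        if "seam_interfaces" in kv:
            val = kv["seam_interfaces"]
            kwargs["seam_interfaces"] = (
                tuple(int(s) for s in val.split(",") if s.strip()) if val else ()
            )
        return cls(**kwargs)


def skew_from_accommodation(spec: LatticeSpec) -> float:
    """Accommodation skew angle (degrees) for a lattice spec.

    Going once around the tube, the N lateral steps of intrinsic rise ``dx``
    accumulate ``N*dx`` of axial offset, but helical closure demands exactly
    ``S*a``.  The deficit is absorbed by tilting the PFs:

        tan(theta) = (S*a - N*dx) / (N*w)

    Zero exactly when ``S*a = N*dx`` (the canonical 13_3 with dx = 3a/13);
    positive (right-handed) when the start helix under-rises (N < 13 for
    3-start), negative (left-handed) when it over-rises (N > 13).
    """
    num = spec.start * spec.monomer_rise - spec.n_pf * spec.lateral_rise
    den = spec.n_pf * spec.inter_pf_spacing
    return math.degrees(math.atan2(num, den))


def moire_from_skew(skew_deg: float, spec: LatticeSpec | None = None) -> float:
    """Projected moire repeat length L (nm) for a given PF skew.

    The surface lattice rotates by one PF spacing ``w`` over the axial
    distance ``L = 2*pi*R / (N * tan|theta|)``, which with ``2*pi*R = N*w``
    reduces to ``L = w / tan|theta|``.  Returns :data:`UNBOUNDED` (inf) for
    straight PFs (theta = 0), which produce no moire.
    """
    if spec is None:
        spec = LatticeSpec()
    t = abs(math.tan(math.radians(skew_deg)))
    if t == 0.0:
        return UNBOUNDED
    return spec.inter_pf_spacing / t


def skew_from_moire(
    moire_nm: float,
    handedness: int | str = "left",
    spec: LatticeSpec | None = None,
) -> float:
    """Signed PF skew (degrees) from a measured moire repeat.

    Inverse of :func:`moire_from_skew`: ``theta = sign * arctan(w / L)``.
    ``handedness`` is ``"left"``/-1 (negative skew, the sense observed for
    the fission-yeast MTs) or ``"right"``/+1.
    """
    if moire_nm <= 0:
        raise ValueError(f"moire repeat must be > 0 nm, got {moire_nm}")
    if spec is None:
        spec = LatticeSpec()
    if isinstance(handedness, str):
        try:
            sign = {"left": -1.0, "right": 1.0}[handedness.lower()]
        except KeyError:
            raise ValueError(f"handedness must be 'left' or 'right', got {handedness!r}")
    else:
        if handedness not in (-1, 1):
            raise ValueError(f"handedness must be -1 or +1, got {handedness}")
        sign = float(handedness)
    if math.isinf(moire_nm):
        return 0.0
    return sign * math.degrees(math.atan(spec.inter_pf_spacing / moire_nm))


def seam_count(spec: LatticeSpec) -> int:
    """Number of A-lattice interfaces in the tube.

    The canonical B-lattice default carries ``S mod 2`` seams (a single seam
    for the usual odd start numbers); an all-A tube has N.
    """
    return len(spec.seam_interfaces)
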