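"""Atomic-model comparison: superposition, RMSD maps, dimer rise, footprints.

Wraps biotite's structure containers behind a small model type with a
selection mechanism, and implements the comparison metrics used for tubulin
structures: least-squares rigid-body superposition on a named core (e.g.
the central beta-sheet of beta-tubulin), per-residue deviation maps,
the axial rise between longitudinally adjacent dimers along a protofilament,
and distance-cutoff interface footprints (the simple geometric stand-in for
buried-surface analysis: every target residue with any atom within the
cutoff of the ligand selection).

Residues of different species are paired by global sequence alignment of
the chains, not by residue numbering.  Coordinates are Angstrom throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "AtomicModel",
    "Selection",
    "superpose",
    "rmsd_map",
    "dimer_rise",
    "footprint",
    "fit_cylinder_axis",
    "POLAR_CHARGED_RESIDUES",
]

logger = logging.getLogger(__name__)

#: three-letter codes counted as polar or charged for footprint filtering
POLAR_CHARGED_RESIDUES = frozenset(
    ["ASP", "GLU", "LYS", "ARG", "HIS", "ASN", "GLN", "SER", "THR", "TYR", "TRP"]
)

_BACKBONE_ATOMS = frozenset(["N", "CA", "C", "O"])


@dataclass(frozen=True)
class Selection:
    """Addresses a subset of a model: chain, residue range, atom names."""

    chain: str | None = None
    res_range: tuple[int, int] | None = None
    atom_names: tuple[str, ...] | None = None

    def mask(self, atoms) -> np.ndarray:
        m = np.ones(atoms.array_length(), dtype=bool)
        if self.chain is not None:
            m &= atoms.chain_id == self.chain
        if self.res_range is not None:
            lo, hi = self.res_range
            m &= (atoms.res_id >= lo) & (atoms.res_id <= hi)
        if self.atom_names is not None:
            m &= np.isin(atoms.atom_name, self.atom_names)
        return m


class AtomicModel:
    """Parsed coordinates with chain/residue/atom hierarchy (Angstrom)."""

    def __init__(self, atoms, name: str = ""):
        if atoms.array_length() == 0:
            raise ValueError("model has no atoms")
        if not np.all(np.isfinite(atoms.coord)):
            raise ValueError("model has non-finite coordinates")
        keys = list(zip(atoms.chain_id, atoms.res_id, atoms.atom_name))
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (chain, residue, atom) keys in model")
        self.atoms = atoms
        self.name = name

    @classmethod
    def load(cls, path: str | Path) -> "AtomicModel":
        """Read a PDB or mmCIF file (first model, no hydrogens removed)."""
        path = Path(path)
        suffix = path.suffix.lower()
        if suffix in (".cif", ".mmcif"):
            import biotite.structure.io.pdbx as pdbx

            f = pdbx.CIFFile.read(str(path))
            atoms = pdbx.get_structure(f, model=1)
        elif suffix in (".pdb", ".ent"):
            import biotite.structure.io.pdb as pdb

            f = pdb.PDBFile.read(str(path))
            atoms = f.get_structure(model=1)
        else:
            raise ValueError(f"unsupported coordinate format: {path.suffix!r}")
        return cls(atoms, name=path.stem)

    @property
    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.atoms.chain_id:
            seen.setdefault(str(c))
        return list(seen)

    def select(self, selection: Selection):
        """AtomArray of the selected atoms."""
        sub = self.atoms[selection.mask(self.atoms)]
        if sub.array_length() == 0:
            raise ValueError(f"selection {selection} matches no atoms")
        return sub

    def transformed(self, transform) -> "AtomicModel":
        """Copy of the model with an affine transformation applied."""
        atoms = self.atoms.copy()
        atoms.coord = transform.apply(atoms.coord.reshape(1, -1, 3))[0]
        return AtomicModel(atoms, name=self.name)


# ---------------------------------------------------------------------------
# residue pairing by sequence alignment
# ---------------------------------------------------------------------------


def _chain_sequence(atoms, chain: str):
    """(ProteinSequence, residue ids) for one chain's CA-bearing residues."""
    from biotite.sequence import ProteinSequence

    m = (atoms.chain_id == chain) & (atoms.atom_name == "CA")
    res_ids = atoms.res_id[m]
    res_names = atoms.res_name[m]
    letters = []
    keep = []
    for rid, rn in zip(res_ids, res_names):
        try:
            letters.append(ProteinSequence.convert_letter_3to1(rn))
            keep.append(int(rid))
        except KeyError:
            continue
    return ProteinSequence("".join(letters)), keep


def pair_residues(
    mobile: AtomicModel,
    reference: AtomicModel,
    chain_pairs: list[tuple[str, str]] | None = None,
) -> list[tuple[str, int, str, int]]:
    """Residue correspondence (mob_chain, mob_res, ref_chain, ref_res).

    Chains are paired in order (or explicitly); residues within a chain
    pair by global sequence alignment with the standard protein
    substitution matrix, so differing residue numbering between species is
    irrelevant.
    """
    import biotite.sequence.align as align

    if chain_pairs is None:
        chain_pairs = list(zip(mobile.chains, reference.chains))
    matrix = align.SubstitutionMatrix.std_protein_matrix()
    pairs = []
    for cm, cr in chain_pairs:
        seq_m, ids_m = _chain_sequence(mobile.atoms, cm)
        seq_r, ids_r = _chain_sequence(reference.atoms, cr)
        if len(ids_m) == 0 or len(ids_r) == 0:
            raise ValueError(f"no alignable residues in chain pair {cm}/{cr}")
        aln = align.align_optimal(
            seq_m, seq_r, matrix, gap_penalty=(-10, -1), terminal_penalty=False
        )[0]
        for i, j in aln.trace:
            if i >= 0 and j >= 0:
                pairs.append((cm, ids_m[i], cr, ids_r[j]))
    return pairs


def _paired_coords(
    mobile: AtomicModel,
    reference: AtomicModel,
    pairs: list[tuple[str, int, str, int]],
    atom_names: tuple[str, ...] = ("CA",),
):
    """Matched coordinate arrays and per-pair atom counts for given pairs."""
    mob_index: dict[tuple[str, int, str], int] = {}
    for k in range(mobile.atoms.array_length()):
        mob_index[
            (str(mobile.atoms.chain_id[k]), int(mobile.atoms.res_id[k]),
             str(mobile.atoms.atom_name[k]))
        ] = k
    ref_index: dict[tuple[str, int, str], int] = {}
    for k in range(reference.atoms.array_length()):
        ref_index[
            (str(reference.atoms.chain_id[k]), int(reference.atoms.res_id[k]),
             str(reference.atoms.atom_name[k]))
        ] = k
    coords_m, coords_r, owners = [], [], []
    for p, (cm, rm, cr, rr) in enumerate(pairs):
        for an in atom_names:
            km = mob_index.get((cm, rm, an))
            kr = ref_index.get((cr, rr, an))
            if km is not None and kr is not None:
                coords_m.append(mobile.atoms.coord[km])
                coords_r.append(reference.atoms.coord[kr])
                owners.append(p)
    if not coords_m:
        raise ValueError("no paired atoms for the requested atom names")
    return np.asarray(coords_m), np.asarray(coords_r), np.asarray(owners)


# ---------------------------------------------------------------------------
# superposition and RMSD
# ---------------------------------------------------------------------------


def superpose(
    mobile: AtomicModel,
    reference: AtomicModel,
    core: Selection | None = None,
    chain_pairs: list[tuple[str, str]] | None = None,
    atom_names: tuple[str, ...] = ("CA",),
):
    """Least-squares rigid-body fit of ``mobile`` onto ``reference``.

    The fit uses only atoms of the ``core`` selection (applied to the
    reference; the corresponding mobile atoms come from the residue
    pairing), e.g. a central beta-sheet.  Returns ``(transform, rmsd)``
    where ``transform`` is biotite's affine transformation and ``rmsd`` is
    over the core atoms after fitting.
    """
    import biotite.structure as struc

    pairs = pair_residues(mobile, reference, chain_pairs)
    if core is not None:
        ref_atoms = reference.atoms
        keep = set()
        cmask = core.mask(ref_atoms)
        allowed = {
            (str(ref_atoms.chain_id[k]), int(ref_atoms.res_id[k]))
            for k in np.where(cmask)[0]
        }
        core_pairs = [p for p in pairs if (p[2], p[3]) in allowed]
        if len(core_pairs) < 3:
            unmatched = sorted(allowed - {(p[2], p[3]) for p in pairs})
            raise ValueError(
                f"core selection pairs fewer than 3 residues; "
                f"unmatched reference residues: {unmatched[:20]}"
            )
    else:
        core_pairs = pairs
    cm, cr, _ = _paired_coords(mobile, reference, core_pairs, atom_names)
    if len(cm) < 3:
        raise ValueError(f"need >= 3 paired atoms for a rigid fit, got {len(cm)}")
    fitted, transform = struc.superimpose(cr, cm)
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - cr) ** 2, axis=1))))
    logger.info("superposed %s onto %s: core RMSD %.3f A over %d atoms",
                mobile.name, reference.name, rmsd, len(cm))
    return transform, rmsd


def rmsd_map(
    mobile: AtomicModel,
    reference: AtomicModel,
    transform=None,
    chain_pairs: list[tuple[str, str]] | None = None,
    atom_names: tuple[str, ...] = ("CA",),
) -> pd.DataFrame:
    """Per-residue deviations (A) of mobile vs reference after superposition.

    ``transform`` is the output of :func:`superpose`; when omitted, the
    models are compared in their current frames.  Residues missing from
    either model are omitted (logged as gaps).  The ``rmsd`` column is the
    per-residue root-mean-square deviation over the selected atoms (for
    CA-only pairing, simply the CA displacement).
    """
    pairs = pair_residues(mobile, reference, chain_pairs)
    cm, cr, owners = _paired_coords(mobile, reference, pairs, atom_names)
    if transform is not None:
        cm = transform.apply(cm.reshape(1, -1, 3))[0]
    d2 = np.sum((cm - cr) ** 2, axis=1)
    rows = []
    for p in np.unique(owners):
        sel = owners == p
        cmn, rm, crn, rr = pairs[p]
        rows.append(
            {
                "mobile_chain": cmn,
                "mobile_res": rm,
                "ref_chain": crn,
                "ref_res": rr,
                "rmsd": float(np.sqrt(d2[sel].mean())),
            }
        )
    n_gap = len(pairs) - len(rows)
    if n_gap:
        logger.info("rmsd_map: %d paired residues lacked the requested atoms", n_gap)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# dimer rise
# ---------------------------------------------------------------------------


def fit_cylinder_axis(coords: np.ndarray, max_radial_cv: float = 0.2) -> np.ndarray:
    """Axis direction of a cylindrical point cloud (unit vector).

    Minimizes the spread of radial distances about a candidate axis through
    the centroid.  Fails (ValueError) when the cloud is not convincingly
    cylindrical - e.g. a short patch of one wall - in which case the caller
    must supply the axis explicitly.
    """
    from scipy.optimize import minimize

    c = coords.mean(axis=0)
    x = coords - c

    def radial_cv(angles):
        t, p = angles
        axis = np.array(
            [np.sin(t) * np.cos(p), np.sin(t) * np.sin(p), np.cos(t)]
        )
        radial = x - np.outer(x @ axis, axis)
        r = np.linalg.norm(radial, axis=1)
        return r.std() / max(r.mean(), 1e-9)

    best = None
    for t0, p0 in [(0.0, 0.0), (np.pi / 2, 0.0), (np.pi / 2, np.pi / 2)]:
        res = minimize(radial_cv, [t0, p0], method="Nelder-Mead",
                       options={"xatol": 1e-6, "fatol": 1e-10})
        if best is None or res.fun < best.fun:
            best = res
    if best.fun > max_radial_cv:
        raise ValueError(
            f"cylinder fit failed (radial scatter {best.fun:.2f}); "
            "supply the MT axis explicitly"
        )
    t, p = best.x
    return np.array([np.sin(t) * np.cos(p), np.sin(t) * np.sin(p), np.cos(t)])


def dimer_rise(
    model: AtomicModel,
    dimer_a: Selection,
    dimer_b: Selection,
    axis: np.ndarray | None = None,
) -> float:
    """Axial rise (A) between two longitudinally adjacent dimers of one PF.

    The rise is the component of the inter-dimer centroid displacement
    along the MT axis (fit from the whole model as a cylinder when not
    supplied).  CA atoms define the centroids.
    """
    ca_a = model.select(
        Selection(dimer_a.chain, dimer_a.res_range, atom_names=("CA",))
    )
    ca_b = model.select(
        Selection(dimer_b.chain, dimer_b.res_range, atom_names=("CA",))
    )
    if axis is None:
        ca_all = model.atoms[model.atoms.atom_name == "CA"]
        axis = fit_cylinder_axis(ca_all.coord)
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    delta = ca_b.coord.mean(axis=0) - ca_a.coord.mean(axis=0)
    return float(abs(delta @ axis))


# ---------------------------------------------------------------------------
# interface footprint
# ---------------------------------------------------------------------------


def footprint(
    model: AtomicModel,
    ligand_selection: Selection,
    target_selection: Selection,
    cutoff: float = 4.0,
    polar_charged_only: bool = False,
    exclude_backbone: bool = False,
) -> list[tuple[str, int, str]]:
    """Target residues with any atom closer than ``cutoff`` (A) to the ligand.

    A distance-cutoff contact footprint (the geometric replacement for
    buried-surface-area analysis).  ``polar_charged_only`` keeps only
    residues in :data:`POLAR_CHARGED_RESIDUES`; ``exclude_backbone``
    ignores backbone atoms when testing distances.
    """
    from scipy.spatial import cKDTree

    lig = model.select(ligand_selection)
    tgt = model.select(target_selection)
    tgt_coord = tgt.coord
    tgt_names = tgt.atom_name
    if exclude_backbone:
        keep = ~np.isin(tgt_names, list(_BACKBONE_ATOMS))
        if not keep.any():
            raise ValueError("no side-chain atoms in target selection")
        tgt = tgt[keep]
        tgt_coord = tgt.coord
    tree = cKDTree(lig.coord)
    dmin, _ = tree.query(tgt_coord, k=1)
    hit = dmin < cutoff
    out = {}
    for k in np.where(hit)[0]:
        key = (str(tgt.chain_id[k]), int(tgt.res_id[k]), str(tgt.res_name[k]))
        out[key] = None
    residues = sorted(out)
    if polar_charged_only:
        residues = [r for r in residues if r[2] in POLAR_CHARGED_RESIDUES]
    logger.info("footprint: %d residues < %.1f A", len(residues), cutoff)
    return residues
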