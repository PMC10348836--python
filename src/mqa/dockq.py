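"""Reference-based interface quality: DockQ for multichain complexes.

DockQ combines three classical CAPRI-style quantities for an interface —
the fraction of native contacts recovered (fnat), the interface backbone
RMSD (iRMS) and the ligand backbone RMSD after receptor superposition
(LRMS) — into one score in [0, 1]:

    DockQ = ( fnat + 1/(1 + (iRMS/1.5)^2) + 1/(1 + (LRMS/8.5)^2) ) / 3

A model with DockQ > 0.23 counts as acceptable.  For a complex of n chains
the score is computed per chain pair (DockQ_ij) and per chain against the
union of all others (DockQ_i); the per-complex label is ALL / SOME / NONE
according to how many one-vs-rest interfaces clear the threshold.

Model and reference residues are matched by SEQRES position, restricted to
residues resolved in both structures.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np

from .structio import Structure, StructureError, common_residue_restriction
from .interfaces import ChainMapping, contacts_between, map_chains

__all__ = [
    "DockQParams",
    "DockQComponents",
    "ComplexEvaluation",
    "superpose",
    "fnat_fnonnat",
    "dockq_score",
    "dockq_pair",
    "dockq_interface",
    "evaluate_complex",
    "classify",
    "success_rate",
    "ACCEPTABLE_DOCKQ",
]

ACCEPTABLE_DOCKQ = 0.23

BACKBONE_ATOMS = ("N", "CA", "C", "O")


@dataclass(frozen=True)
class DockQParams:
    """Internal DockQ constants, exposed as configuration.

    fnat contacts use any heavy-atom pair within ``fnat_cutoff``; interface
    residues for iRMS come from the native structure at
    ``interface_cutoff``; the two RMSD scales enter the combination formula.
    """

    fnat_cutoff: float = 5.0
    interface_cutoff: float = 10.0
    irms_scale: float = 1.5
    lrms_scale: float = 8.5
    threshold: float = ACCEPTABLE_DOCKQ


@dataclass
class DockQComponents:
    fnat: float
    fnonnat: float
    irms: float
    lrms: float
    dockq: float

    def as_dict(self) -> Dict[str, float]:
        return {
            "fnat": self.fnat,
            "fnonnat": self.fnonnat,
            "irms": self.irms,
            "lrms": self.lrms,
            "dockq": self.dockq,
        }


@dataclass
class ComplexEvaluation:
    dockq_ij: Dict[Tuple[str, str], DockQComponents]
    dockq_i: Dict[str, DockQComponents]
    label: str
    mapping: ChainMapping
    mm_score: Optional[float] = None
    threshold: float = ACCEPTABLE_DOCKQ

    @property
    def min_dockq_i(self) -> float:
        return min(c.dockq for c in self.dockq_i.values())

    @property
    def max_dockq_i(self) -> float:
        return max(c.dockq for c in self.dockq_i.values())

    @property
    def min_dockq_ij(self) -> float:
        return min(c.dockq for c in self.dockq_ij.values())

    @property
    def max_dockq_ij(self) -> float:
        return max(c.dockq for c in self.dockq_ij.values())

    def as_dict(self) -> Dict:
        return {
            "dockq_ij": {"-".join(k): v.as_dict() for k, v in self.dockq_ij.items()},
            "dockq_i": {k: v.as_dict() for k, v in self.dockq_i.items()},
            "min_dockq_i": self.min_dockq_i,
            "max_dockq_i": self.max_dockq_i,
            "min_dockq_ij": self.min_dockq_ij,
            "max_dockq_ij": self.max_dockq_ij,
            "label": self.label,
            "mm_score": self.mm_score,
            "threshold": self.threshold,
            "chain_mapping": self.mapping.pairs,
        }


# ---------------------------------------------------------------------------
# Rigid superposition (Kabsch)


def superpose(
    coords_ref: np.ndarray, coords_mov: np.ndarray
) -> Tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of *coords_mov* onto *coords_ref*.

    Returns (rotation, translation, rmsd) such that
    ``coords_mov @ rotation.T + translation`` best fits *coords_ref*; the
    rotation is proper (det = +1).  Near-collinear point sets are flagged
    with a warning but still superposed.
    """
    P = np.asarray(coords_ref, dtype=float)
    Q = np.asarray(coords_mov, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("coordinate arrays must both be N x 3")
    n = P.shape[0]
    if n < 3:
        raise ValueError("need at least 3 points to superpose")
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - cp, Q - cq
    H = Q0.T @ P0
    U, S, Vt = np.linalg.svd(H)
    if S[1] <= 1e-9 * max(S[0], 1.0):
        warnings.warn("near-degenerate (collinear) point set in superposition")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cp - R @ cq
    diff = (Q @ R.T + t) - P
    rmsd = float(np.sqrt((diff**2).sum() / n))
    return R, t, rmsd


# ---------------------------------------------------------------------------
# Components


def fnat_fnonnat(
    native_contacts: Set[FrozenSet], model_contacts: Set[FrozenSet]
) -> Tuple[float, float]:
    """Fraction of native contacts kept, and of model contacts that are new.

    An empty model contact set yields (0, 0) by convention; an empty native
    set is an error because the interface is then undefined.
    """
    if not native_contacts:
        raise StructureError("no native interface: empty native contact set")
    fnat = len(native_contacts & model_contacts) / len(native_contacts)
    fnonnat = (
        len(model_contacts - native_contacts) / len(model_contacts)
        if model_contacts
        else 0.0
    )
    return fnat, fnonnat


def dockq_score(
    fnat: float, irms: float, lrms: float, params: DockQParams = DockQParams()
) -> float:
    return (
        fnat
        + 1.0 / (1.0 + (irms / params.irms_scale) ** 2)
        + 1.0 / (1.0 + (lrms / params.lrms_scale) ** 2)
    ) / 3.0


# ---------------------------------------------------------------------------
# Interface scoring machinery


def _restricted_contacts(
    struct: Structure,
    ligand: str,
    receptors: Sequence[str],
    allowed: Dict[str, Set[int]],
    cutoff: float,
) -> Set[FrozenSet]:
    """Heavy-atom contact keys between ligand and receptor chains, keeping
    only residues whose SEQRES position is in *allowed* for their chain."""
    out: Set[FrozenSet] = set()
    for rec in receptors:
        for c in contacts_between(struct, ligand, rec, cutoff, scheme="heavy_atom"):
            if c.res_a in allowed[ligand] and c.res_b in allowed[rec]:
                out.add(frozenset({(c.chain_a, c.res_a), (c.chain_b, c.res_b)}))
    return out


def _translate_contacts(
    contacts: Set[FrozenSet], pos_maps: Dict[str, Dict[int, int]],
    chain_map: Dict[str, str],
) -> Set[FrozenSet]:
    """Re-express model contacts in native chain ids and SEQRES positions."""
    out: Set[FrozenSet] = set()
    for pair in contacts:
        items = []
        for chain_id, pos in pair:
            items.append((chain_map[chain_id], pos_maps[chain_id][pos]))
        out.add(frozenset(items))
    return out


def _backbone_coords(
    model: Structure,
    native: Structure,
    residues: Iterable[Tuple[str, int]],
    restriction: Dict[str, List[Tuple[int, int]]],
    inverse_map: Dict[str, str],
) -> Tuple[np.ndarray, np.ndarray]:
    """Paired backbone coordinates (native, model) over *residues*.

    *residues* are (native_chain_id, native_seqres_pos); only atoms present
    in both structures for a residue contribute.  Falls back to Cα when a
    residue has no shared backbone atom.
    """
    nat_pts: List[np.ndarray] = []
    mod_pts: List[np.ndarray] = []
    rest_by_native: Dict[str, Dict[int, int]] = {}
    for m_id, pairs in restriction.items():
        rest_by_native[m_id] = {np_: mp for mp, np_ in pairs}
    for n_chain, n_pos in sorted(residues):
        m_chain = inverse_map[n_chain]
        m_pos = rest_by_native[m_chain].get(n_pos)
        if m_pos is None:
            continue
        n_res = native.chain(n_chain).residue_at_seqres(n_pos)
        m_res = model.chain(m_chain).residue_at_seqres(m_pos)
        shared = [a for a in BACKBONE_ATOMS if a in n_res.atoms and a in m_res.atoms]
        if not shared and "CA" in n_res.atoms and "CA" in m_res.atoms:
            shared = ["CA"]
        for a in shared:
            nat_pts.append(n_res.atoms[a])
            mod_pts.append(m_res.atoms[a])
    return np.asarray(nat_pts), np.asarray(mod_pts)


def _score_interface(
    model: Structure,
    native: Structure,
    ligand_native: str,
    receptor_natives: Sequence[str],
    mapping: ChainMapping,
    params: DockQParams,
) -> DockQComponents:
    """Shared implementation of pairwise and one-vs-rest DockQ."""
    inv = mapping.inverse
    ligand_model = inv[ligand_native]
    receptor_models = [inv[r] for r in receptor_natives]

    restriction = common_residue_restriction(model, native, mapping)
    allowed_native: Dict[str, Set[int]] = {}
    allowed_model: Dict[str, Set[int]] = {}
    pos_model_to_native: Dict[str, Dict[int, int]] = {}
    for m_id, pairs in restriction.items():
        n_id = mapping.pairs[m_id]
        allowed_model[m_id] = {mp for mp, _ in pairs}
        allowed_native[n_id] = {np_ for _, np_ in pairs}
        pos_model_to_native[m_id] = dict(pairs)

    native_contacts = _restricted_contacts(
        native, ligand_native, receptor_natives, allowed_native, params.fnat_cutoff
    )
    if not native_contacts:
        raise StructureError(
            f"native interface {ligand_native} vs {receptor_natives} has no contacts"
        )
    model_contacts = _translate_contacts(
        _restricted_contacts(
            model, ligand_model, receptor_models, allowed_model, params.fnat_cutoff
        ),
        pos_model_to_native,
        mapping.pairs,
    )
    fnat, fnonnat = fnat_fnonnat(native_contacts, model_contacts)

    # interface residues: native definition, wider cutoff
    interface_pairs = _restricted_contacts(
        native, ligand_native, receptor_natives, allowed_native,
        params.interface_cutoff,
    )
    interface_residues: Set[Tuple[str, int]] = set()
    for pair in interface_pairs:
        interface_residues.update(pair)

    nat_i, mod_i = _backbone_coords(
        model, native, interface_residues, restriction, inv
    )
    if len(nat_i) < 3:
        raise StructureError("fewer than 3 shared interface backbone atoms")
    _, _, irms = superpose(nat_i, mod_i)

    # LRMS: superpose on receptor backbone, measure over ligand backbone
    receptor_residues = {
        (n_id, p) for n_id in receptor_natives for p in allowed_native[n_id]
    }
    ligand_residues = {(ligand_native, p) for p in allowed_native[ligand_native]}
    nat_r, mod_r = _backbone_coords(model, native, receptor_residues, restriction, inv)
    nat_l, mod_l = _backbone_coords(model, native, ligand_residues, restriction, inv)
    if len(nat_r) < 3 or len(nat_l) < 1:
        raise StructureError("too few backbone atoms for LRMS")
    R, t, _ = superpose(nat_r, mod_r)
    moved = mod_l @ R.T + t
    lrms = float(np.sqrt(((moved - nat_l) ** 2).sum() / len(nat_l)))

    return DockQComponents(
        fnat=fnat,
        fnonnat=fnonnat,
        irms=irms,
        lrms=lrms,
        dockq=dockq_score(fnat, irms, lrms, params),
    )


def dockq_pair(
    model: Structure,
    native: Structure,
    chain_i: str,
    chain_j: str,
    mapping: Optional[ChainMapping] = None,
    params: DockQParams = DockQParams(),
) -> DockQComponents:
    """Pairwise DockQ_ij for native chains i and j.

    The larger chain (by residues resolved in both structures, ties broken
    lexicographically) acts as receptor, the smaller as ligand.
    """
    if mapping is None:
        mapping = map_chains(model, native)
    restriction = common_residue_restriction(model, native, mapping)
    inv = mapping.inverse
    sizes = {c: len(restriction[inv[c]]) for c in (chain_i, chain_j)}
    ligand, receptor = sorted((chain_i, chain_j), key=lambda c: (sizes[c], c))[0], None
    receptor = chain_j if ligand == chain_i else chain_i
    return _score_interface(model, native, ligand, [receptor], mapping, params)


def dockq_interface(
    model: Structure,
    native: Structure,
    ligand_chain: str,
    mapping: Optional[ChainMapping] = None,
    params: DockQParams = DockQParams(),
) -> DockQComponents:
    """One-vs-rest DockQ_i: chain i as ligand, all remaining chains jointly
    as one rigid receptor."""
    if mapping is None:
        mapping = map_chains(model, native)
    receptors = [c for c in native.chain_ids if c != ligand_chain]
    if not receptors:
        raise StructureError("one-vs-rest needs >= 2 chains")
    return _score_interface(model, native, ligand_chain, receptors, mapping, params)


# ---------------------------------------------------------------------------
# Per-complex evaluation


def classify(dockq_i: Sequence[float], threshold: float = ACCEPTABLE_DOCKQ) -> str:
    """ALL if every interface clears the threshold (>=), NONE if none does,
    SOME otherwise."""
    vals = list(dockq_i)
    if not vals:
        raise ValueError("empty DockQ_i vector")
    above = [v >= threshold for v in vals]
    if all(above):
        return "ALL"
    if not any(above):
        return "NONE"
    return "SOME"


def evaluate_complex(
    model: Structure,
    native: Structure,
    threshold: float = ACCEPTABLE_DOCKQ,
    mapping: Optional[ChainMapping] = None,
    mm_score: Optional[float] = None,
    params: Optional[DockQParams] = None,
) -> ComplexEvaluation:
    """Full multi-interface evaluation of *model* against *native*.

    Computes DockQ_ij for every native chain pair with at least one contact
    and DockQ_i for every chain with at least one inter-chain contact, then
    aggregates and labels the complex.
    """
    if params is None:
        params = DockQParams(threshold=threshold)
    if mapping is None:
        mapping = map_chains(model, native)

    dockq_ij: Dict[Tuple[str, str], DockQComponents] = {}
    touching: Set[str] = set()
    for a, b in itertools.combinations(native.chain_ids, 2):
        if contacts_between(native, a, b, params.fnat_cutoff, "heavy_atom"):
            dockq_ij[(a, b)] = dockq_pair(model, native, a, b, mapping, params)
            touching.update((a, b))
    dockq_i = {
        c: dockq_interface(model, native, c, mapping, params)
        for c in native.chain_ids
        if c in touching
    }
    if not dockq_i:
        raise StructureError("no chain in the native structure has inter-chain contacts")
    label = classify([c.dockq for c in dockq_i.values()], threshold)
    return ComplexEvaluation(
        dockq_ij=dockq_ij,
        dockq_i=dockq_i,
        label=label,
        mapping=mapping,
        mm_score=mm_score,
        threshold=threshold,
    )


def success_rate(
    evaluations: Sequence[ComplexEvaluation], threshold: float = ACCEPTABLE_DOCKQ
) -> float:
    """Fraction of complexes whose worst one-vs-rest interface is acceptable
    (min DockQ_i strictly greater than the threshold)."""
    if not evaluations:
        raise ValueError("empty evaluation list")
    hits = sum(1 for e in evaluations if e.min_dockq_i > threshold)
    return hits / len(evaluations)
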