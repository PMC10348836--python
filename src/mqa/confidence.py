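"""Reference-free interface confidence: pDockQ and pDockQ2.

Both scores push an interface feature X through the same four-parameter
sigmoid

    score(X) = L / (1 + exp(-k (X - x0))) + b

pDockQ (per chain pair) uses interface size and quality only:

    X = <pLDDT>_int * ln(N_int)

pDockQ2 (per chain i, over all of that chain's interfaces) additionally
folds in AlphaFold's predicted aligned error, so that a large, confidently
packed but wrongly placed interface — invisible to pDockQ — is penalised:

    X_i = < 1 / (1 + (PAE/d0)^2) >_int * <pLDDT>_int ,   d0 = 10 Å

The PAE average runs over the inter-chain contact pairs of chain i, each
pair taking the mean of its two directed PAE entries; <pLDDT>_int is the
mean pLDDT over the unique residues on both sides of those contacts.  The
published pDockQ2 sigmoid coefficients are L = 1.31, x0 = 84.733,
k = 0.075, b = 0.005, obtained by nonlinear least squares against actual
DockQ_i values; the same fitting routine is exposed here so new
coefficients can be calibrated on any model set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import curve_fit

from .structio import ConfidenceData, Structure, StructureError
from .interfaces import ContactPair, one_vs_rest_interface, contacts_between

__all__ = [
    "SigmoidCoeffs",
    "PDOCKQ2_COEFFS",
    "PDockQ2Params",
    "InterfaceFeatures",
    "sigmoid",
    "pdockq_features",
    "pdockq_pair",
    "pdockq2_features",
    "pdockq2_chain",
    "pdockq2_complex",
    "fit_sigmoid",
    "SigmoidFit",
]


@dataclass(frozen=True)
class SigmoidCoeffs:
    L: float
    x0: float
    k: float
    b: float

    def __post_init__(self) -> None:
        if self.L <= 0 or self.k <= 0:
            raise ValueError("sigmoid needs L > 0 and k > 0")


#: Published pDockQ2 calibration (fit against DockQ_i on AlphaFold-Multimer
#: models).  pDockQ has no packaged default: supply coefficients explicitly
#: or calibrate with :func:`fit_sigmoid`.
PDOCKQ2_COEFFS = SigmoidCoeffs(L=1.31, x0=84.733, k=0.075, b=0.005)


@dataclass(frozen=True)
class PDockQ2Params:
    d0: float = 10.0
    contact_cutoff: float = 8.0
    contact_scheme: str = "cb"
    coeffs: SigmoidCoeffs = PDOCKQ2_COEFFS
    nint_mode: str = "contact_pairs"  # or "unique_residues"
    pae_over: str = "contact_pairs"   # or "all_pairs"
    plddt_side: str = "both"          # or "ligand"

    def __post_init__(self) -> None:
        if self.d0 <= 0 or self.contact_cutoff <= 0:
            raise ValueError("d0 and contact_cutoff must be > 0")


@dataclass
class InterfaceFeatures:
    n_int: int
    mean_plddt_int: float
    mean_pae_term: Optional[float] = None

    @property
    def x_pdockq(self) -> float:
        if self.n_int < 1:
            raise ValueError("pDockQ feature needs >= 1 contact")
        return self.mean_plddt_int * math.log(self.n_int)

    @property
    def x_pdockq2(self) -> float:
        if self.mean_pae_term is None:
            raise ValueError("no PAE term available")
        return self.mean_pae_term * self.mean_plddt_int


def sigmoid(x: float, coeffs: SigmoidCoeffs) -> float:
    """L / (1 + exp(-k (x - x0))) + b — strictly increasing, range (b, L+b).

    Evaluated via tanh for numerical stability at extreme arguments.
    """
    z = coeffs.k * (x - coeffs.x0)
    return coeffs.L * 0.5 * (1.0 + math.tanh(z / 2.0)) + coeffs.b


# ---------------------------------------------------------------------------
# shared residue lookup


def _plddt_lookup(model: Structure, conf: ConfidenceData) -> Dict[Tuple[str, int], float]:
    """(chain_id, seqres_pos) -> pLDDT, via the model's resolved order."""
    gidx = model.global_index()
    out: Dict[Tuple[str, int], float] = {}
    for chain in model.chains:
        for pos, k in chain.seqres_to_atom.items():
            out[(chain.chain_id, pos)] = float(conf.plddt[gidx[(chain.chain_id, k)]])
    return out


def _pae_index(model: Structure) -> Dict[Tuple[str, int], int]:
    """(chain_id, seqres_pos) -> global PAE/pLDDT index."""
    gidx = model.global_index()
    out: Dict[Tuple[str, int], int] = {}
    for chain in model.chains:
        for pos, k in chain.seqres_to_atom.items():
            out[(chain.chain_id, pos)] = gidx[(chain.chain_id, k)]
    return out


def _mean_interface_plddt(
    contacts: Sequence[ContactPair],
    plddt: Dict[Tuple[str, int], float],
    ligand: Optional[str] = None,
) -> float:
    residues = set()
    for c in contacts:
        residues.add((c.chain_a, c.res_a))
        residues.add((c.chain_b, c.res_b))
    if ligand is not None:
        residues = {r for r in residues if r[0] == ligand}
    return float(np.mean([plddt[r] for r in residues]))


# ---------------------------------------------------------------------------
# pDockQ (per chain pair)


def pdockq_features(
    model: Structure,
    conf: ConfidenceData,
    chain_i: str,
    chain_j: str,
    cutoff: float = 8.0,
    nint_mode: str = "contact_pairs",
) -> InterfaceFeatures:
    contacts = contacts_between(model, chain_i, chain_j, cutoff, scheme="cb")
    if not contacts:
        raise StructureError(f"no contacts between chains {chain_i} and {chain_j}")
    plddt = _plddt_lookup(model, conf)
    residues = set()
    for c in contacts:
        residues.add((c.chain_a, c.res_a))
        residues.add((c.chain_b, c.res_b))
    n_int = len(contacts) if nint_mode == "contact_pairs" else len(residues)
    return InterfaceFeatures(
        n_int=n_int,
        mean_plddt_int=float(np.mean([plddt[r] for r in residues])),
    )


def pdockq_pair(
    model: Structure,
    conf: ConfidenceData,
    chain_i: str,
    chain_j: str,
    coeffs: SigmoidCoeffs,
    cutoff: float = 8.0,
    nint_mode: str = "contact_pairs",
) -> float:
    """Size-and-pLDDT interface confidence for one chain pair."""
    feats = pdockq_features(model, conf, chain_i, chain_j, cutoff, nint_mode)
    return sigmoid(feats.x_pdockq, coeffs)


def pdockq_chain(
    model: Structure,
    conf: ConfidenceData,
    chain: str,
    coeffs: SigmoidCoeffs,
    cutoff: float = 8.0,
) -> float:
    """Per-chain pDockQ summary: the most confident pairwise interface of
    *chain* (max over partners with >= 1 contact)."""
    scores = []
    for other in model.chain_ids:
        if other == chain:
            continue
        try:
            scores.append(pdockq_pair(model, conf, chain, other, coeffs, cutoff))
        except StructureError:
            continue
    if not scores:
        raise StructureError(f"chain {chain} has no inter-chain contacts")
    return max(scores)


# ---------------------------------------------------------------------------
# pDockQ2 (per chain, PAE-aware)


def pdockq2_features(
    model: Structure,
    conf: ConfidenceData,
    ligand_chain: str,
    params: PDockQ2Params = PDockQ2Params(),
) -> InterfaceFeatures:
    """Interface features of chain i over all its inter-chain contacts."""
    iface = one_vs_rest_interface(
        model, ligand_chain, params.contact_cutoff, params.contact_scheme
    )
    if not iface.contacts:
        raise StructureError(f"chain {ligand_chain} has no inter-chain contacts")
    if conf.pae is None:
        raise StructureError("PAE matrix required for pDockQ2")
    idx = _pae_index(model)
    plddt = _plddt_lookup(model, conf)

    if params.pae_over == "contact_pairs":
        pair_list = [((c.chain_a, c.res_a), (c.chain_b, c.res_b)) for c in iface.contacts]
    else:  # all inter-chain residue pairs between interface residues
        lig_res = sorted(r for r in iface.interface_residues if r[0] == ligand_chain)
        rec_res = sorted(r for r in iface.interface_residues if r[0] != ligand_chain)
        pair_list = [(a, b) for a in lig_res for b in rec_res]
    terms = []
    for a, b in pair_list:
        ia, ib = idx[a], idx[b]
        pae = 0.5 * (conf.pae[ia, ib] + conf.pae[ib, ia])
        terms.append(1.0 / (1.0 + (pae / params.d0) ** 2))
    mean_pae_term = float(np.mean(terms))

    ligand = ligand_chain if params.plddt_side == "ligand" else None
    mean_plddt = _mean_interface_plddt(iface.contacts, plddt, ligand)
    n_int = (
        len(iface.contacts)
        if params.nint_mode == "contact_pairs"
        else len(iface.interface_residues)
    )
    return InterfaceFeatures(
        n_int=n_int, mean_plddt_int=mean_plddt, mean_pae_term=mean_pae_term
    )


def pdockq2_chain(
    model: Structure,
    conf: ConfidenceData,
    ligand_chain: str,
    params: PDockQ2Params = PDockQ2Params(),
) -> float:
    """PAE-aware per-chain interface confidence (pDockQ2)."""
    feats = pdockq2_features(model, conf, ligand_chain, params)
    return sigmoid(feats.x_pdockq2, params.coeffs)


def pdockq2_complex(
    model: Structure,
    conf: ConfidenceData,
    params: PDockQ2Params = PDockQ2Params(),
) -> Dict[str, object]:
    """pDockQ2 for every chain with inter-chain contacts, plus the minimum.

    Chains without any inter-chain contact are reported in ``no_contact``
    rather than given a floor score.
    """
    if len(model.chains) < 2:
        raise StructureError("pDockQ2 needs >= 2 chains")
    scores: Dict[str, float] = {}
    missing: List[str] = []
    for chain in model.chain_ids:
        try:
            scores[chain] = pdockq2_chain(model, conf, chain, params)
        except StructureError:
            missing.append(chain)
    if not scores:
        raise StructureError("no chain has any inter-chain contact")
    return {
        "per_chain": scores,
        "min_pdockq2": min(scores.values()),
        "no_contact": missing,
    }


# ---------------------------------------------------------------------------
# Sigmoid calibration


@dataclass
class SigmoidFit:
    coeffs: SigmoidCoeffs
    rmse: float
    n: int


def fit_sigmoid(
    xs: Sequence[float],
    ys: Sequence[float],
    seed: int = 0,
    n_restarts: int = 3,
) -> SigmoidFit:
    """Calibrate sigmoid coefficients against observed DockQ values.

    Nonlinear least squares over (L, x0, k, b), started from
    (L=1, x0=median(x), k=0.05, b=0) with bounds L in (0, 2], k in (0, 1],
    b in [0, 0.5], x0 within the data range; up to *n_restarts* seeded
    jittered restarts on failure.
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if len(xs) != len(ys):
        raise ValueError("xs and ys differ in length")
    if len(xs) < 20:
        raise ValueError("need >= 20 points to calibrate the sigmoid")
    if np.any(ys < 0) or np.any(ys > 1):
        raise ValueError("response values must lie in [0, 1]")
    if np.ptp(ys) == 0:
        raise ValueError("degenerate response: all y values are equal")

    def model(x, L, x0, k, b):
        return L / (1.0 + np.exp(-k * (x - x0))) + b

    lo = [1e-6, float(xs.min()), 1e-6, 0.0]
    hi = [2.0, float(xs.max()), 1.0, 0.5]
    p0 = np.array([1.0, float(np.median(xs)), 0.05, 0.0])
    rng = np.random.default_rng(seed)
    last_err: Optional[Exception] = None
    for attempt in range(n_restarts + 1):
        start = p0 if attempt == 0 else np.clip(
            p0 * (1.0 + 0.3 * rng.standard_normal(4)) + [0, 0, 0, 0.01], lo, hi
        )
        try:
            popt, _ = curve_fit(
                model, xs, ys, p0=start, bounds=(lo, hi), maxfev=20000
            )
            resid = model(xs, *popt) - ys
            return SigmoidFit(
                coeffs=SigmoidCoeffs(*[float(v) for v in popt]),
                rmse=float(np.sqrt(np.mean(resid**2))),
                n=len(xs),
            )
        except RuntimeError as exc:
            last_err = exc
    raise RuntimeError(f"sigmoid fit did not converge: {last_err}")
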