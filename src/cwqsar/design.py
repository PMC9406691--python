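"""Fragment-guided computer-aided design of substituted analogues.

A trained correlation-weight model decomposes predicted activity into
additive attribute contributions, so the sign of a fragment's weight says
whether adding that fragment promotes or suppresses activity.  This module
(1) classifies attribute keys as activity promoters/suppressors by their
weight sign stability across independent optimization runs, and (2)
enumerates analogues of a template bearing a monosubstituted phenyl ring by
grafting simple aliphatic substituents at the ortho, meta and para sites and
scoring each analogue with a designated model.
"""

from __future__ import annotations

from dataclasses import dataclass

from rdkit import Chem

from .mc_model import CWModel, dcw, predict_smiles, profile_for
from .records import AttributeKey
from .smiles_attributes import SmilesError, canonize_smiles

#: aliphatic substituents used by default: methyl, ethyl, isopropyl
DEFAULT_SUBSTITUENTS = ("C", "CC", "C(C)C")
POSITIONS = ("ortho", "meta", "para")


class DesignError(ValueError):
    """Raised when a template lacks the required monosubstituted phenyl."""


@dataclass
class FragmentVerdict:
    key: AttributeKey
    runs_positive: int
    runs_negative: int
    verdict: str  # promoter_increase | promoter_decrease | undefined


@dataclass
class DesignCandidate:
    smiles: str
    predicted_pKi: float
    fragments_added: list[AttributeKey]
    template_id: str
    substituent: str = ""
    position: str = ""


def fragment_contributions(models: list[CWModel]) -> list[FragmentVerdict]:
    """Sign-stability verdict for every attribute key across runs.

    A key is an activity promoter (``promoter_increase``) iff its weight is
    positive in every run, a suppressor (``promoter_decrease``) iff negative
    in every run, and ``undefined`` otherwise — including keys blocked in any
    run.
    """
    if not models:
        raise ValueError("need at least one model")
    keys = set()
    for m in models:
        keys |= set(m.weights)
    verdicts = []
    for key in sorted(keys, key=lambda k: (k.category, k.key)):
        if any(key in m.blocked or key not in m.weights for m in models):
            verdicts.append(FragmentVerdict(key, 0, 0, "undefined"))
            continue
        cws = [m.weights[key] for m in models]
        pos = sum(1 for w in cws if w > 0)
        neg = sum(1 for w in cws if w < 0)
        if pos == len(cws):
            verdict = "promoter_increase"
        elif neg == len(cws):
            verdict = "promoter_decrease"
        else:
            verdict = "undefined"
        verdicts.append(FragmentVerdict(key, pos, neg, verdict))
    return verdicts


def _phenyl_sites(mol: Chem.Mol) -> dict[str, int]:
    """Atom indices of the ortho/meta/para CH sites of a monosubstituted
    phenyl ring (lowest-index site chosen where two are equivalent)."""
    for ring in mol.GetRingInfo().AtomRings():
        if len(ring) != 6:
            continue
        atoms = [mol.GetAtomWithIdx(i) for i in ring]
        if not all(a.GetIsAromatic() and a.GetSymbol() == "C" for a in atoms):
            continue
        ring_set = set(ring)
        ipso = [
            a for a in atoms
            if any(nb.GetIdx() not in ring_set for nb in a.GetNeighbors())
        ]
        if len(ipso) != 1:
            continue
        if any(
            a.GetTotalNumHs() != 1
            for a in atoms if a.GetIdx() != ipso[0].GetIdx()
        ):
            continue
        # walk the ring starting at ipso
        order = [ipso[0].GetIdx()]
        prev = None
        while len(order) < 6:
            current = mol.GetAtomWithIdx(order[-1])
            nxt = [
                nb.GetIdx() for nb in current.GetNeighbors()
                if nb.GetIdx() in ring_set and nb.GetIdx() != prev
                and nb.GetIdx() not in order
            ]
            prev = order[-1]
            order.append(nxt[0])
        ortho = min(order[1], order[5])
        meta = min(order[2], order[4])
        para = order[3]
        return {"ortho": ortho, "meta": meta, "para": para}
    raise DesignError("template has no monosubstituted phenyl ring")


def attach_substituent(template_smiles: str, substituent: str,
                       position: str) -> str:
    """Graft a substituent onto the phenyl ring and return canonical SMILES.

    The attachment is molecular-graph surgery (combine, bond, sanitize,
    re-canonize), never raw string concatenation: the attribute extraction
    downstream depends on the canonical form.
    """
    if position not in POSITIONS:
        raise ValueError(f"position must be one of {POSITIONS}")
    mol = Chem.MolFromSmiles(template_smiles)
    if mol is None:
        raise SmilesError(f"cannot parse SMILES: {template_smiles!r}")
    frag = Chem.MolFromSmiles(substituent)
    if frag is None:
        raise SmilesError(f"cannot parse substituent: {substituent!r}")
    site = _phenyl_sites(mol)[position]
    combo = Chem.RWMol(Chem.CombineMols(mol, frag))
    combo.AddBond(site, mol.GetNumAtoms(), Chem.BondType.SINGLE)
    Chem.SanitizeMol(combo)
    return canonize_smiles(Chem.MolToSmiles(combo))


def _added_fragments(template: str, candidate: str) -> list[AttributeKey]:
    base = profile_for(canonize_smiles(template)).counts
    new = profile_for(candidate).counts
    added = []
    for key, count in new.items():
        extra = count - base.get(key, 0)
        added.extend([key] * max(extra, 0))
    return sorted(added, key=lambda k: (k.category, k.key))


def enumerate_designs(
    template: str,
    model: CWModel,
    substituents=DEFAULT_SUBSTITUENTS,
    positions=POSITIONS,
    template_id: str = "template",
) -> list[DesignCandidate]:
    """One scored candidate per (substituent, position) pair."""
    candidates = []
    for sub in substituents:
        for pos in positions:
            smiles = attach_substituent(template, sub, pos)
            candidates.append(DesignCandidate(
                smiles=smiles,
                predicted_pKi=predict_smiles(model, smiles),
                fragments_added=_added_fragments(template, smiles),
                template_id=template_id,
                substituent=sub,
                position=pos,
            ))
    return candidates


def rank_designs(candidates: list[DesignCandidate]) -> list[DesignCandidate]:
    """Descending predicted activity; ties broken by canonical SMILES."""
    return sorted(candidates, key=lambda c: (-c.predicted_pKi, c.smiles))


def fragment_effect(model: CWModel, template: str, substituent: str,
                    position: str) -> float:
    """Model-implied activity increment of grafting one substituent.

    Equals slope·(DCW(candidate) − DCW(template)) by linearity of the
    calibration line.
    """
    cand = attach_substituent(template, substituent, position)
    base = canonize_smiles(template)
    return model.slope_C1 * (
        dcw(profile_for(cand), model) - dcw(profile_for(base), model)
    )
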