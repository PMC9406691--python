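"""SMILES-derived optimal-descriptor attributes.

The conformation-independent QSAR approach reads descriptors straight off a
canonical SMILES string.  Local attributes are the single tokens (S), adjacent
token pairs (SS) and adjacent token triples (SSS); global attributes summarise
whole-molecule features: heteroatom presence (NOSP), halogen presence (HALO),
unsaturation/stereo bonds (BOND), co-occurring element pairs (ATOMPAIR),
element-count statistics (Xmax.n) and a composite presence fingerprint (HARD).

Every attribute is rendered as a fixed-width 12-character '.'-padded key so
that attribute multisets from different molecules can be compared, counted and
weighted.  Conventions for the local keys:

* a closing parenthesis is rewritten to ``'('`` before key formation, so
  branch boundaries are direction-free;
* in a pair key the two token texts are written in descending byte order,
  each left-justified in a 4-character dotted field;
* in a triple key the middle token stays in the middle field and the two end
  tokens are written in descending byte order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

from rdkit import Chem
from rdkit import RDLogger

from .records import KEY_WIDTH, AttributeKey, AttributeProfile

RDLogger.DisableLog("rdApp.*")

# Two-character SMILES symbols kept whole during tokenization.
DIGRAPHS = ("Cl", "Br", "@@")

PAIR_ELEMENTS = ("F", "Cl", "Br", "N", "O", "S", "P", "B2", "B3")


class SmilesError(ValueError):
    """Raised when a SMILES string cannot be parsed."""


@dataclass(frozen=True)
class Token:
    """One SMILES symbol.

    ``text`` is the normalized symbol (')' stored as '('); ``raw`` keeps the
    original spelling so the token stream can reproduce the input string.
    Ring-closure escapes ``%NN`` are kept whole.
    """

    text: str
    position: int
    raw: str = ""

    def __post_init__(self) -> None:
        if not self.text:
            raise ValueError("empty token")
        if not self.raw:
            object.__setattr__(self, "raw", self.text)


def canonize_smiles(raw: str) -> str:
    """Return the canonical SMILES of ``raw`` under one fixed engine.

    Canonicalization is idempotent and invariant to the input atom order;
    unparseable input raises :class:`SmilesError` naming the offender.
    """
    mol = Chem.MolFromSmiles(raw)
    if mol is None:
        raise SmilesError(f"cannot parse SMILES: {raw!r}")
    return Chem.MolToSmiles(mol)


def _mol(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesError(f"cannot parse SMILES: {smiles!r}")
    return mol


def tokenize(smiles: str) -> list[Token]:
    """Split a SMILES string into its symbol stream.

    Two-character element symbols (Cl, Br) and the '@@' chirality mark are
    single tokens; '%NN' ring closures are kept whole; every other character
    is its own token.  ')' is normalized to '(' in ``text``.
    """
    if not smiles:
        raise SmilesError("empty SMILES")
    tokens: list[Token] = []
    i = 0
    pos = 0
    n = len(smiles)
    while i < n:
        if smiles[i] == "%" and len(smiles[i + 1 : i + 3]) == 2 and smiles[i + 1 : i + 3].isdigit():
            raw = smiles[i : i + 3]
        elif smiles[i : i + 2] in DIGRAPHS:
            raw = smiles[i : i + 2]
        else:
            raw = smiles[i]
        text = "(" if raw == ")" else raw
        tokens.append(Token(text=text, position=pos, raw=raw))
        i += len(raw)
        pos += 1
    return tokens


def _pad(text: str, width: int) -> str:
    return text.ljust(width, ".")


def s_key(token_text: str) -> AttributeKey:
    return AttributeKey(_pad(token_text, KEY_WIDTH), "S")


def ss_key(a: str, b: str) -> AttributeKey:
    hi, lo = (a, b) if a >= b else (b, a)
    return AttributeKey(_pad(hi, 4) + _pad(lo, KEY_WIDTH - 4), "SS")


def sss_key(a: str, mid: str, c: str) -> AttributeKey:
    hi, lo = (a, c) if a >= c else (c, a)
    return AttributeKey(_pad(hi, 4) + _pad(mid, 4) + _pad(lo, 4), "SSS")


def local_attributes(tokens: Sequence[Token]) -> list[AttributeKey]:
    """Emit the S, SS and SSS keys of a token stream, with multiplicity."""
    texts = [t.text for t in tokens]
    keys = [s_key(t) for t in texts]
    keys += [ss_key(a, b) for a, b in zip(texts, texts[1:])]
    keys += [sss_key(a, m, c) for a, m, c in zip(texts, texts[1:], texts[2:])]
    return keys


# --- global attributes -----------------------------------------------------


def _bits(flags: Iterable[bool]) -> str:
    return "".join("1" if f else "0" for f in flags)


def _has_element(mol: Chem.Mol, symbol: str) -> bool:
    return any(a.GetSymbol() == symbol for a in mol.GetAtoms())


def _bond_flags(mol: Chem.Mol) -> tuple[bool, bool, bool]:
    double = any(b.GetBondType() == Chem.BondType.DOUBLE for b in mol.GetBonds())
    triple = any(b.GetBondType() == Chem.BondType.TRIPLE for b in mol.GetBonds())
    stereo = any(b.GetStereo() != Chem.BondStereo.STEREONONE for b in mol.GetBonds())
    return double, triple, stereo


def nosp_key(mol: Chem.Mol) -> AttributeKey:
    bits = _bits(_has_element(mol, e) for e in ("N", "O", "S", "P"))
    return AttributeKey("NOSP" + bits + "0000", "NOSP")


def halo_key(mol: Chem.Mol) -> AttributeKey:
    bits = _bits(_has_element(mol, e) for e in ("F", "Cl", "Br"))
    return AttributeKey("HALO" + bits + "00000", "HALO")


def bond_key(mol: Chem.Mol) -> AttributeKey:
    bits = _bits(_bond_flags(mol))
    return AttributeKey("BOND" + bits + "00000", "BOND")


def atompair_keys(mol: Chem.Mol) -> list[AttributeKey]:
    """One key per co-occurring pair of halogen/heteroatom/unsaturation marks.

    ``B2``/``B3`` stand for the presence of a double/triple bond; pair members
    are ordered by the canonical element list and rendered as
    ``'++++X---Y==='`` padded to 12 characters.
    """
    double, triple, _ = _bond_flags(mol)
    present = [e for e in PAIR_ELEMENTS[:7] if _has_element(mol, e)]
    if double:
        present.append("B2")
    if triple:
        present.append("B3")
    present.sort(key=PAIR_ELEMENTS.index)
    keys = []
    for i, a in enumerate(present):
        for b in present[i + 1 :]:
            text = a.rjust(5, "+") + "---" + b
            keys.append(AttributeKey(text.ljust(KEY_WIDTH, "="), "ATOMPAIR"))
    return keys


def default_element_stat(mol: Chem.Mol, element: str) -> int:
    """Default ``Xmax.n`` statistic.

    For C: the number of terminal methyl groups (degree-1 aliphatic carbons
    bearing three hydrogens).  For N/O/S: the number of non-aromatic atoms of
    that element.  Capped at 9 so the code stays one digit.
    """
    if element == "C":
        n = sum(
            1
            for a in mol.GetAtoms()
            if a.GetSymbol() == "C"
            and not a.GetIsAromatic()
            and a.GetDegree() == 1
            and a.GetTotalNumHs() == 3
        )
    else:
        n = sum(
            1
            for a in mol.GetAtoms()
            if a.GetSymbol() == element and not a.GetIsAromatic()
        )
    return min(n, 9)


ElementStatRule = Callable[[Chem.Mol, str], int]


def element_stat_keys(
    mol: Chem.Mol, rule: ElementStatRule = default_element_stat
) -> list[AttributeKey]:
    return [
        AttributeKey(_pad(f"{e}max.{rule(mol, e)}", KEY_WIDTH), "XMAX")
        for e in ("C", "N", "O", "S")
    ]


#: Ordered feature list behind the composite HARD fingerprint.  The code is a
#: presence bit-string; the list is a package convention and configurable.
DEFAULT_HARD_FEATURES: tuple[tuple[str, Callable[[Chem.Mol], bool]], ...] = (
    ("N", lambda m: _has_element(m, "N")),
    ("O", lambda m: _has_element(m, "O")),
    ("S", lambda m: _has_element(m, "S")),
    ("P", lambda m: _has_element(m, "P")),
    ("F", lambda m: _has_element(m, "F")),
    ("Cl", lambda m: _has_element(m, "Cl")),
    ("Br", lambda m: _has_element(m, "Br")),
    ("double", lambda m: _bond_flags(m)[0]),
    ("triple", lambda m: _bond_flags(m)[1]),
    ("aromatic", lambda m: any(a.GetIsAromatic() for a in m.GetAtoms())),
    ("ring", lambda m: m.GetRingInfo().NumRings() > 0),
)


def hard_key(
    mol: Chem.Mol, features=DEFAULT_HARD_FEATURES
) -> AttributeKey:
    bits = _bits(f(mol) for _, f in features)
    return AttributeKey(_pad(bits, KEY_WIDTH), "HARD")


def global_attributes(
    smiles: str,
    element_stat_rule: ElementStatRule = default_element_stat,
    hard_features=DEFAULT_HARD_FEATURES,
) -> list[AttributeKey]:
    """All whole-molecule attribute keys of a canonical SMILES."""
    mol = _mol(smiles)
    keys = [nosp_key(mol), halo_key(mol), bond_key(mol)]
    keys += atompair_keys(mol)
    keys += element_stat_keys(mol, element_stat_rule)
    keys.append(hard_key(mol, hard_features))
    return keys


def smiles_attribute_profile(
    molecule_id: str,
    smiles: str,
    element_stat_rule: ElementStatRule = default_element_stat,
) -> AttributeProfile:
    """AttributeProfile of the SMILES-based (local + global) attributes."""
    profile = AttributeProfile(molecule_id)
    for key in local_attributes(tokenize(smiles)):
        profile.add(key)
    for key in global_attributes(smiles, element_stat_rule):
        profile.add(key)
    return profile
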