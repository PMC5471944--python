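"""Drug-identifier normalization and matching against chemical nodes.

Compounds arrive as SMILES strings and are matched to chemical nodes through
InChIKeys: the query SMILES is desalted (largest fragment kept), hashed to
its standard InChIKey, and matched on the key's first 14 characters — the
connectivity block, which is independent of stereochemistry — so that all
stereoisomers and salt forms of a compound resolve to the same merged
(``CIDm``) node, mirroring how the chemical database itself folds them.

The cheminformatics toolkit sits behind a four-method backend protocol so
the rest of the package never imports chemistry machinery; graph and
pathfinding code runs without a chemistry stack installed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Protocol

from .graph import EvidenceGraph

INCHIKEY_RE = re.compile(r"^[A-Z]{14}-[A-Z]{10}-[A-Z]$")


class ChemistryError(ValueError):
    """Unparsable or otherwise invalid chemical input."""

    def __init__(self, message: str, smiles: str | None = None) -> None:
        super().__init__(message)
        self.smiles = smiles


class ChemBackend(Protocol):
    """Narrow cheminformatics interface the package depends on."""

    def canonical_smiles(self, smiles: str) -> str: ...

    def split_fragments(self, smiles: str) -> list[str]: ...

    def heavy_atom_count(self, smiles: str) -> int: ...

    def inchikey(self, smiles: str, strip_stereo: bool) -> str: ...


class RDKitBackend:
    """Standard-InChI implementation on top of RDKit."""

    def __init__(self) -> None:
        from rdkit import Chem, RDLogger

        RDLogger.DisableLog("rdApp.*")
        self._chem = Chem

    def _mol(self, smiles: str):
        mol = self._chem.MolFromSmiles(smiles)
        if mol is None:
            raise ChemistryError(f"unparsable SMILES: {smiles!r}", smiles)
        return mol

    def canonical_smiles(self, smiles: str) -> str:
        return self._chem.MolToSmiles(self._mol(smiles))

    def split_fragments(self, smiles: str) -> list[str]:
        mol = self._mol(smiles)
        frags = self._chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
        return [self._chem.MolToSmiles(f) for f in frags]

    def heavy_atom_count(self, smiles: str) -> int:
        return self._mol(smiles).GetNumHeavyAtoms()

    def inchikey(self, smiles: str, strip_stereo: bool) -> str:
        mol = self._mol(smiles)
        if strip_stereo:
            self._chem.RemoveStereochemistry(mol)
        key = self._chem.MolToInchiKey(mol)
        if not key:
            raise ChemistryError(
                f"InChIKey generation failed for {smiles!r}", smiles
            )
        return key


_default_backend: ChemBackend | None = None


def get_backend() -> ChemBackend:
    global _default_backend
    if _default_backend is None:
        _default_backend = RDKitBackend()
    return _default_backend


@dataclass(frozen=True)
class ChemicalRecord:
    """A normalized compound: desalted SMILES and its InChIKey."""

    input_smiles: str
    desalted_smiles: str
    inchikey: str

    def __post_init__(self) -> None:
        if not INCHIKEY_RE.match(self.inchikey):
            raise ChemistryError(
                f"malformed InChIKey {self.inchikey!r}", self.input_smiles
            )

    @property
    def connectivity_block(self) -> str:
        """First 14 characters of the key: skeleton only, stereo-free."""
        return self.inchikey[:14]


def strip_salts(smiles: str, backend: ChemBackend | None = None) -> str:
    """Keep the largest fragment of a (possibly multi-fragment) SMILES.

    Salt and solvate components are dot-separated fragments; the fragment
    with the most heavy atoms is the parent compound.  Ties break to the
    lexicographically smallest canonical fragment SMILES.
    """
    backend = backend or get_backend()
    fragments = backend.split_fragments(smiles)
    if not fragments:
        raise ChemistryError(f"no fragments in SMILES {smiles!r}", smiles)
    counts = {f: backend.heavy_atom_count(f) for f in fragments}
    biggest = max(counts.values())
    return min(f for f, c in counts.items() if c == biggest)


def to_inchikey(
    smiles: str,
    stereo: str = "strip",
    backend: ChemBackend | None = None,
) -> ChemicalRecord:
    """Desalt a SMILES and hash it to its standard InChIKey.

    With ``stereo="strip"`` (the default) stereo descriptors are removed
    before hashing, so enantiomers and other stereoisomers share a key; with
    ``stereo="keep"`` the full stereo-aware key is produced.
    """
    if stereo not in ("keep", "strip"):
        raise ValueError(f"stereo must be 'keep' or 'strip', got {stereo!r}")
    backend = backend or get_backend()
    desalted = strip_salts(smiles, backend)
    key = backend.inchikey(desalted, strip_stereo=stereo == "strip")
    return ChemicalRecord(
        input_smiles=smiles,
        desalted_smiles=backend.canonical_smiles(desalted),
        inchikey=key,
    )


def match_chemical(
    smiles: str,
    graph: EvidenceGraph,
    backend: ChemBackend | None = None,
) -> str | None:
    """Resolve a SMILES to a chemical node id, or ``None`` if absent.

    The graph's alias map is scanned for InChIKey aliases (full 27-character
    keys or bare 14-character connectivity blocks) and matched on the
    connectivity block, making the lookup stereo-insensitive — consistent
    with the merged-compound (``CIDm``) node convention.
    """
    record = to_inchikey(smiles, stereo="strip", backend=backend)
    block = record.connectivity_block
    hits = {
        node
        for alias, node in graph.aliases.items()
        if _looks_like_inchikey(alias) and alias[:14] == block
    }
    if not hits:
        return None
    return min(hits)


def _looks_like_inchikey(alias: str) -> bool:
    return bool(
        INCHIKEY_RE.match(alias) or re.match(r"^[A-Z]{14}$", alias)
    )
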