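"""Reading, normalizing and writing RNA structures and base-pair annotations.

A :class:`Structure` is an ordered list of single-letter chains of residues,
each residue carrying its author key ``(chain_id, residue_number,
insertion_code)`` and atom coordinates in angstroms.  Normalization applied on
read follows the conventions used when preparing coordinate files for
graph-based analysis:

* multi-model (NMR) inputs keep only the first model;
* multi-character chain identifiers are remapped deterministically to the
  first unused symbol in ``A-Z a-z 0-9`` (encounter order);
* atom serial numbers are ignored on input (overflowed serial fields are
  tolerated) and re-sequenced from 1 on output.

Base-pair annotations are read from a minimal one-pair-per-line text dialect
(``A1-A8 : WC``); a fixture-grade distance annotator is provided so that the
synthetic structures in :mod:`rnamotifs.synthetic` round-trip without any
external annotation tool.
"""

from __future__ import annotations

import logging
import math
import re
import string
from dataclasses import dataclass, field
from pathlib import Path

from .errors import CapacityError, FormatError, ReferenceError_

logger = logging.getLogger(__name__)

#: residue key: (chain_id, author residue number, insertion code or "")
ResidueKey = tuple[str, int, str]

CANONICAL_BASES = ("A", "U", "G", "C")
#: complementary base combinations accepted as WC (G-U wobble included)
WC_COMPLEMENTS = {
    frozenset({"A", "U"}),
    frozenset({"G", "C"}),
    frozenset({"G", "U"}),
}

COVALENT = "COVALENT"
WC = "WC"
NONWC = "NONWC"

_CHAIN_SYMBOLS = string.ascii_uppercase + string.ascii_lowercase + string.digits


@dataclass
class Residue:
    key: ResidueKey
    base: str  # A, U, G, C or OTHER
    atoms: list[tuple[str, float, float, float]] = field(default_factory=list)

    def atom(self, name: str) -> tuple[float, float, float] | None:
        for aname, x, y, z in self.atoms:
            if aname == name:
                return (x, y, z)
        return None


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class Structure:
    structure_id: str
    chains: list[Chain] = field(default_factory=list)
    source_format: str = "PDB"
    model_used: int = 1
    #: original chain id -> normalized single-character id
    chain_remap: dict[str, str] = field(default_factory=dict)

    def __iter__(self):
        for chain in self.chains:
            yield from chain.residues

    @property
    def n_residues(self) -> int:
        return sum(len(c) for c in self.chains)

    def residue(self, key: ResidueKey) -> Residue:
        res = self.find_residue(key)
        if res is None:
            raise ReferenceError_(f"residue key {key!r} not found in {self.structure_id}")
        return res

    def find_residue(self, key: ResidueKey) -> Residue | None:
        for chain in self.chains:
            if chain.chain_id != key[0]:
                continue
            for res in chain.residues:
                if res.key == key:
                    return res
        return None


@dataclass
class InteractionSet:
    """Unordered residue-pair interactions, each with a nonempty type set."""

    interactions: list[tuple[ResidueKey, ResidueKey, frozenset[str]]] = field(
        default_factory=list
    )

    def __len__(self) -> int:
        return len(self.interactions)

    def of_type(self, itype: str):
        return [ia for ia in self.interactions if itype in ia[2]]


def _normalize_base(resname: str) -> str:
    name = resname.strip().upper()
    return name if name in CANONICAL_BASES else "OTHER"


# ---------------------------------------------------------------------------
# reading


def read_structure(path, fmt: str = "auto") -> Structure:
    """Read a PDB or mmCIF file into a normalized :class:`Structure`.

    ``fmt`` is one of ``"PDB"``, ``"mmCIF"`` or ``"auto"`` (detect from the
    file suffix, falling back to content sniffing).
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: file does not exist")
    if fmt == "auto":
        suffix = path.suffix.lower()
        if suffix in {".cif", ".mmcif"}:
            fmt = "mmCIF"
        elif suffix in {".pdb", ".ent"}:
            fmt = "PDB"
        else:
            head = path.read_text(errors="replace").lstrip()[:5]
            fmt = "mmCIF" if head.startswith("data_") else "PDB"
    if fmt == "PDB":
        structure = _read_pdb_text(path.read_text(), structure_id=path.stem)
    elif fmt == "mmCIF":
        structure = _read_mmcif(path)
    else:
        raise FormatError(f"unknown format {fmt!r}")
    _remap_chain_ids(structure)
    return structure


def read_structure_text(text: str, structure_id: str = "anon") -> Structure:
    """Parse PDB-format text directly (convenience for in-memory fixtures)."""
    structure = _read_pdb_text(text, structure_id=structure_id)
    _remap_chain_ids(structure)
    return structure


def _read_pdb_text(text: str, structure_id: str) -> Structure:
    structure = Structure(structure_id=structure_id, source_format="PDB")
    chains: dict[str, Chain] = {}
    residues: dict[tuple[str, int, str], Residue] = {}
    model = 0
    seen_model_records = False
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.startswith("MODEL"):
            seen_model_records = True
            model += 1
            continue
        if line.startswith("ENDMDL"):
            continue
        # startswith, not fixed columns: wide (overflowed) serial fields may
        # spill into the record-name field
        if not line.startswith(("ATOM", "HETATM")):
            continue
        if seen_model_records and model != 1:
            continue  # first model only
        try:
            fields = _parse_atom_line(line)
        except (ValueError, IndexError) as exc:
            raise FormatError(f"{structure_id}: unparseable ATOM record at line {lineno}: {exc}") from exc
        name, resname, chain_id, resnum, icode, x, y, z = fields
        if not all(math.isfinite(v) for v in (x, y, z)):
            raise FormatError(f"{structure_id}: non-finite coordinate at line {lineno}")
        rkey = (chain_id, resnum, icode)
        if rkey not in residues:
            res = Residue(key=rkey, base=_normalize_base(resname))
            residues[rkey] = res
            if chain_id not in chains:
                chains[chain_id] = Chain(chain_id=chain_id)
                structure.chains.append(chains[chain_id])
            chains[chain_id].residues.append(res)
        residues[rkey].atoms.append((name, x, y, z))
    structure.model_used = 1
    return structure


def _parse_atom_line(line):
    """Parse one ATOM/HETATM record, fixed-column first, whitespace fallback.

    The fallback tolerates the serial-number overflow dialect in which wide
    serial fields (>=100000) shift the remaining columns.
    """
    serial_field = line[6:11]
    fixed_ok = (
        line[:6] in ("ATOM  ", "HETATM")
        and serial_field.strip().isdigit()
        and (len(line) < 12 or line[11] == " ")
    )
    if fixed_ok:
        name = line[12:16].strip()
        resname = line[17:20].strip()
        chain_id = line[21].strip() or " "
        resnum = int(line[22:26])
        icode = line[26].strip()
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
        return name, resname, chain_id, resnum, icode, x, y, z
    tokens = line.split()
    # ATOM serial name resname chain resnum[icode] x y z ...
    if len(tokens) < 9:
        raise ValueError("too few fields")
    name, resname, chain_id = tokens[2], tokens[3], tokens[4]
    m = re.fullmatch(r"(-?\d+)([A-Za-z]?)", tokens[5])
    if m is None:
        raise ValueError(f"bad residue number {tokens[5]!r}")
    resnum, icode = int(m.group(1)), m.group(2)
    x, y, z = (float(t) for t in tokens[6:9])
    return name, resname, chain_id, resnum, icode, x, y, z


def _read_mmcif(path: Path) -> Structure:
    import gemmi

    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"{path}: {exc}") from exc
    structure = Structure(structure_id=st.name or path.stem, source_format="mmCIF")
    if len(st) == 0:
        return structure
    model = st[0]  # first model only
    for ch in model:
        chain = Chain(chain_id=ch.name)
        for res in ch:
            icode = res.seqid.icode.strip()
            rkey = (ch.name, res.seqid.num, icode)
            residue = Residue(key=rkey, base=_normalize_base(res.name))
            for at in res:
                residue.atoms.append((at.name, at.pos.x, at.pos.y, at.pos.z))
            chain.residues.append(residue)
        structure.chains.append(chain)
    structure.model_used = 1
    return structure


def _remap_chain_ids(structure: Structure) -> None:
    """Remap multi-character chain ids to the first unused single symbol."""
    if len(structure.chains) > len(_CHAIN_SYMBOLS):
        raise CapacityError(
            f"{structure.structure_id}: {len(structure.chains)} chains exceed the "
            f"{len(_CHAIN_SYMBOLS)}-chain single-character capacity"
        )
    used = {c.chain_id for c in structure.chains if len(c.chain_id) == 1}
    remap: dict[str, str] = {}
    for chain in structure.chains:
        if len(chain.chain_id) == 1:
            remap[chain.chain_id] = chain.chain_id
            continue
        new_id = next((s for s in _CHAIN_SYMBOLS if s not in used), None)
        if new_id is None:
            raise CapacityError(
                f"{structure.structure_id}: no unused single-character chain id left"
            )
        used.add(new_id)
        remap[chain.chain_id] = new_id
        old = chain.chain_id
        chain.chain_id = new_id
        for res in chain.residues:
            res.key = (new_id, res.key[1], res.key[2])
        logger.info("remapped chain %r -> %r", old, new_id)
    structure.chain_remap = remap


# ---------------------------------------------------------------------------
# chain filtering


def filter_rna_chains(s: Structure) -> Structure:
    """Keep exactly the chains containing at least one A/U/G/C residue.

    Modified (``OTHER``) residues inside qualifying chains are retained.
    Idempotent; may return a structure with zero chains.
    """
    kept = [c for c in s.chains if any(r.base in CANONICAL_BASES for r in c.residues)]
    return Structure(
        structure_id=s.structure_id,
        chains=kept,
        source_format=s.source_format,
        model_used=s.model_used,
        chain_remap=dict(s.chain_remap),
    )


# ---------------------------------------------------------------------------
# annotations

_ANNOTATION_LINE = re.compile(
    r"^\s*(?P<ca>\S)(?P<na>-?\d+)-(?P<cb>\S)(?P<nb>-?\d+)\s*:\s*(?P<type>WC|NONWC)\s*$"
)


def _backbone_interactions(s: Structure) -> list[tuple[ResidueKey, ResidueKey, set[str]]]:
    out = []
    for chain in s.chains:
        for r1, r2 in zip(chain.residues, chain.residues[1:]):
            out.append((r1.key, r2.key, {COVALENT}))
    return out


def _resolve_key(s: Structure, chain_id: str, number: int) -> ResidueKey:
    exact = s.find_residue((chain_id, number, ""))
    if exact is not None:
        return exact.key
    candidates = [r.key for r in s if r.key[0] == chain_id and r.key[1] == number]
    if len(candidates) == 1:
        return candidates[0]
    raise ReferenceError_(f"annotation refers to unknown residue {chain_id}{number}")


def read_annotation(text: str, s: Structure) -> InteractionSet:
    """Parse pairing lines (``A1-A8 : WC``) and add backbone covalent edges.

    Every pair of chain-adjacent residues yields one COVALENT interaction
    regardless of the pairing lines; a residue pair listed with several types
    accumulates them into one type set.
    """
    pairs: dict[frozenset[ResidueKey], set[str]] = {}
    for ka, kb, types in _backbone_interactions(s):
        pairs.setdefault(frozenset((ka, kb)), set()).update(types)
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        m = _ANNOTATION_LINE.match(line)
        if m is None:
            raise FormatError(f"annotation line {lineno} not in dialect: {line!r}")
        ka = _resolve_key(s, m.group("ca"), int(m.group("na")))
        kb = _resolve_key(s, m.group("cb"), int(m.group("nb")))
        if ka == kb:
            raise FormatError(f"annotation line {lineno} pairs a residue with itself")
        pairs.setdefault(frozenset((ka, kb)), set()).add(m.group("type"))
    interactions = [
        (min(pair), max(pair), frozenset(types)) for pair, types in pairs.items()
    ]
    interactions.sort()
    return InteractionSet(interactions=interactions)


def naive_annotate(
    s: Structure,
    min_dist: float = 8.5,
    max_dist: float = 12.0,
) -> InteractionSet:
    """Fixture-grade distance annotator (not a production base-pair caller).

    Emits WC for complementary bases (A-U, G-C, G-U) whose C1'-C1' distance
    lies in ``[min_dist, max_dist]`` angstroms, matched greedily by distance
    with at most one partner per residue, plus covalent backbone edges.
    Never emits NONWC.
    """
    residues = list(s)
    coords: list[tuple[ResidueKey, str, tuple[float, float, float]]] = []
    for res in residues:
        c1 = res.atom("C1'")
        if c1 is None:
            logger.warning("residue %r has no C1' atom; skipped by naive_annotate", res.key)
            continue
        coords.append((res.key, res.base, c1))
    candidates = []
    for i in range(len(coords)):
        for j in range(i + 1, len(coords)):
            ka, ba, pa = coords[i]
            kb, bb, pb = coords[j]
            if frozenset({ba, bb}) not in WC_COMPLEMENTS:
                continue
            d = math.dist(pa, pb)
            if min_dist <= d <= max_dist:
                candidates.append((d, ka, kb))
    candidates.sort()
    matched: set[ResidueKey] = set()
    pairs: dict[frozenset[ResidueKey], set[str]] = {}
    for _, ka, kb in candidates:
        if ka in matched or kb in matched:
            continue
        matched.update((ka, kb))
        pairs[frozenset((ka, kb))] = {WC}
    for ka, kb, types in _backbone_interactions(s):
        pairs.setdefault(frozenset((ka, kb)), set()).update(types)
    interactions = [
        (min(pair), max(pair), frozenset(types)) for pair, types in pairs.items()
    ]
    interactions.sort()
    return InteractionSet(interactions=interactions)


# ---------------------------------------------------------------------------
# writing


def write_motif_pdb(s: Structure, members: list[ResidueKey] | None = None) -> str:
    """Render the member residues as PDB text, serials re-numbered from 1.

    ``members=None`` writes the whole structure.  Chain and residue
    identifiers are preserved; an empty member list produces a header-only
    file with a logged warning.
    """
    if members is None:
        members = [r.key for r in s]
    member_set = set(members)
    for key in member_set:
        s.residue(key)  # raises ReferenceError_ for unknown keys
    lines = [f"REMARK   motif extracted from {s.structure_id}"]
    if not member_set:
        logger.warning("write_motif_pdb called with an empty member list")
    serial = 0
    for chain in s.chains:
        wrote_any = False
        for res in chain.residues:
            if res.key not in member_set:
                continue
            wrote_any = True
            resname = res.base if res.base != "OTHER" else "UNK"
            for name, x, y, z in res.atoms:
                serial += 1
                atom_name = name if len(name) >= 4 else f" {name:<3s}"
                lines.append(
                    f"ATOM  {serial:5d} {atom_name:<4.4s} {resname:>3s} {chain.chain_id}"
                    f"{res.key[1]:4d}{res.key[2] or ' '}   "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00"
                )
        if wrote_any:
            lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"
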