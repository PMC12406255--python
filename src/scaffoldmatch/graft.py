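"""Epitope grafting: splice bioactive sequences into peptide scaffolds.

A :class:`GraftDesign` records one splice — replacing a 1-based inclusive
span of the scaffold sequence with an insert — and the resulting chimera
inherits the scaffold's terminal modifications and disulfide count.
Multi-span grafts (epitope pieces placed in both helices and the loop)
are expressed as sequential splices, applied C-terminal-first so that
every span can be stated in the original scaffold's own numbering.

The packaged design config (``data/vhti_pepitem_designs.toml``) reproduces the
synthesized VhTI-pepitem chimera series: the pepitem loop epitope
(EQGAELS) embedded in the loop of a norleucine-substituted VhTI scaffold
variant in several registers, plus one design distributing the full
pepitem sequence over helices and loop.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field, replace
from pathlib import Path

if sys.version_info >= (3, 11):
    import tomllib
else:  # pragma: no cover
    import tomli as tomllib

__all__ = [
    "PeptideSpec",
    "GraftDesign",
    "build_chimera",
    "enumerate_designs",
    "apply_substitution",
    "load_design_config",
    "vhti_pepitem_designs",
    "AA_ALPHABET",
]

#: 20 standard residues plus Z for norleucine.
AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYZ")


@dataclass(frozen=True)
class PeptideSpec:
    """A peptide sequence with terminal modifications and disulfide count."""

    sequence: str
    n_term: str = "free"  # {free, acetyl}
    c_term: str = "free"  # {free, amide}
    n_disulfides: int = 0
    name: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("sequence must be non-empty")
        bad = set(self.sequence) - AA_ALPHABET
        if bad:
            raise ValueError(
                f"invalid residue code(s) {''.join(sorted(bad))!r} in sequence"
            )
        if self.n_term not in ("free", "acetyl"):
            raise ValueError(f"n_term must be free|acetyl, got {self.n_term!r}")
        if self.c_term not in ("free", "amide"):
            raise ValueError(f"c_term must be free|amide, got {self.c_term!r}")
        if self.n_disulfides < 0:
            raise ValueError("n_disulfides must be >= 0")
        if self.n_disulfides > self.sequence.count("C") // 2:
            raise ValueError(
                f"{self.n_disulfides} disulfides impossible with "
                f"{self.sequence.count('C')} cysteines"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class GraftDesign:
    name: str
    scaffold: PeptideSpec
    replaced_span: tuple[int, int]  # 1-based inclusive on the scaffold sequence
    insert: str
    chimera: PeptideSpec
    provenance: list[str] = field(default_factory=list)


def build_chimera(
    scaffold: PeptideSpec,
    span: tuple[int, int],
    insert: str,
    name: str = "",
) -> GraftDesign:
    """Replace scaffold residues span[0]..span[1] (1-based, inclusive) by insert.

    An empty insert deletes the span.  The chimera inherits the
    scaffold's terminal modifications and disulfide count; an insert
    that adds cysteines triggers a warning since the recorded disulfide
    count may no longer describe the folded product.
    """
    start, end = span
    seq = scaffold.sequence
    if not (1 <= start <= end <= len(seq)):
        raise ValueError(
            f"span {span} out of range for scaffold of length {len(seq)}"
        )
    bad = set(insert) - AA_ALPHABET
    if bad:
        raise ValueError(f"invalid residue code(s) {''.join(sorted(bad))!r} in insert")
    import logging

    log = logging.getLogger(__name__)
    if "C" in insert:
        log.warning(
            "insert %r adds cysteines; disulfide count carried from scaffold",
            insert,
        )
    chimera_seq = seq[: start - 1] + insert + seq[end:]
    if not chimera_seq:
        raise ValueError("splice deletes the entire scaffold sequence")
    n_ss = scaffold.n_disulfides
    if n_ss > chimera_seq.count("C") // 2:
        n_ss = chimera_seq.count("C") // 2
        log.warning(
            "splice removes cysteines; disulfide count reduced from %d to %d",
            scaffold.n_disulfides, n_ss,
        )
    chimera = PeptideSpec(
        sequence=chimera_seq,
        n_term=scaffold.n_term,
        c_term=scaffold.c_term,
        n_disulfides=n_ss,
        name=name or f"{scaffold.name}[{start}-{end}>{insert}]",
    )
    return GraftDesign(
        name=chimera.name,
        scaffold=scaffold,
        replaced_span=(start, end),
        insert=insert,
        chimera=chimera,
        provenance=[f"splice {start}-{end} -> {insert or '(deletion)'}"],
    )


def enumerate_designs(
    scaffold: PeptideSpec,
    span: tuple[int, int],
    epitope: str,
    registers: list[tuple[int, int]],
) -> list[GraftDesign]:
    """One design per (offset, length) window of the epitope spliced into span.

    Offsets are 0-based into the epitope.  Designs are ordered by
    (offset, length); windows producing identical chimera sequences are
    collapsed with merged provenance.
    """
    if not registers:
        raise ValueError("register list must be non-empty")
    for off, length in registers:
        if off < 0 or length < 0 or off + length > len(epitope):
            raise ValueError(
                f"window (offset={off}, length={length}) exceeds epitope bounds"
            )
    designs: dict[str, GraftDesign] = {}
    for off, length in sorted(registers):
        insert = epitope[off : off + length]
        d = build_chimera(scaffold, span, insert,
                          name=f"{scaffold.name or 'scaffold'}+{insert}")
        d.provenance = [f"epitope window offset={off} length={length}"]
        key = d.chimera.sequence
        if key in designs:
            designs[key].provenance.extend(d.provenance)
        else:
            designs[key] = d
    return list(designs.values())


def apply_substitution(p: PeptideSpec, position: int, new_residue: str) -> PeptideSpec:
    """Point substitution at a 1-based position (e.g. Met -> norleucine Z)."""
    if new_residue not in AA_ALPHABET or len(new_residue) != 1:
        raise ValueError(f"invalid residue code {new_residue!r}")
    if not 1 <= position <= len(p.sequence):
        raise ValueError(f"position {position} out of range 1..{len(p.sequence)}")
    seq = p.sequence[: position - 1] + new_residue + p.sequence[position:]
    return replace(p, sequence=seq)


def _spec_from_table(tbl: dict) -> PeptideSpec:
    return PeptideSpec(
        sequence=tbl["sequence"],
        n_term=tbl.get("n_term", "free"),
        c_term=tbl.get("c_term", "free"),
        n_disulfides=tbl.get("n_disulfides", 0),
        name=tbl.get("name", ""),
    )


def load_design_config(path: str | Path) -> dict[str, object]:
    """Parse a TOML design config into concrete designs.

    Returns a dict with keys ``scaffold`` (PeptideSpec), ``designs``
    (list of GraftDesign, one per [[design]] table; multi-splice designs
    apply their splices in listed order, each span in the coordinates of
    the current intermediate), and ``peptides`` (extra standalone
    [[peptide]] specs, e.g. the linear epitope itself).
    """
    with open(path, "rb") as fh:
        cfg = tomllib.load(fh)
    scaffold = _spec_from_table(cfg["scaffold"])
    designs = []
    for entry in cfg.get("design", []):
        current = scaffold
        provenance = []
        for splice in entry["splices"]:
            start, end = splice["span"]
            d = build_chimera(current, (start, end), splice["insert"],
                              name=entry["name"])
            provenance.extend(d.provenance)
            current = d.chimera
        designs.append(
            GraftDesign(
                name=entry["name"],
                scaffold=scaffold,
                replaced_span=tuple(entry["splices"][0]["span"]),
                insert=entry["splices"][0]["insert"],
                chimera=current,
                provenance=provenance,
            )
        )
    peptides = [_spec_from_table(t) for t in cfg.get("peptide", [])]
    return {"scaffold": scaffold, "designs": designs, "peptides": peptides}


def vhti_pepitem_designs() -> dict[str, object]:
    """The packaged VhTI-pepitem chimera series design config."""
    return load_design_config(Path(__file__).parent / "data" / "vhti_pepitem_designs.toml")
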