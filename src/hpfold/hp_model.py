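"""Hydrophobic-polar (HP) sequence handling.

An HP sequence classifies each residue of a protein chain as hydrophobic
(H) or polar (P).  Benchmark collections print HP sequences in two
run-length dialects:

* **prefix** — a multiplier precedes the symbol or parenthesised group it
  repeats: ``2H5P`` is ``HHPPPPP``, ``3(2H4P)`` is ``HHPPPP`` three times.
* **caret** — an exponent follows the symbol or group: ``H^2P^5`` is
  ``HHPPPPP``, ``(HP)^2`` is ``HPHP``.  Groups may nest.

``parse_hp_notation`` expands either dialect (auto-detected by the presence
of ``^``); ``fasta_to_hp`` maps one-letter amino-acid codes onto the H/P
alphabet using the residue classes

    H: A G I L M F P W V
    P: R N D C E Q H K S T Y

Note the deliberately coarse chemistry of these classes (proline counts as
hydrophobic, histidine as polar); an override map can be supplied for
studies that prefer a different partition.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

__all__ = [
    "HPSequence",
    "HPNotationError",
    "H_CLASS",
    "P_CLASS",
    "parse_hp_notation",
    "compress_hp",
    "fasta_to_hp",
    "read_fasta",
    "hydrophobic_fraction",
]

H_CLASS = frozenset("AGILMFPWV")
P_CLASS = frozenset("RNDCEQHKSTY")

_AMBIGUOUS = frozenset("BJOUXZ")


class HPNotationError(ValueError):
    """Raised for malformed run-length HP notation.

    Carries the 0-based ``position`` of the offending character.
    """

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (position {position})")
        self.position = position


@dataclass(frozen=True)
class HPSequence:
    """An expanded HP residue string plus the notation it came from.

    ``source_notation`` keeps the original text (run-length notation or
    amino-acid sequence) for provenance; ``residues`` is always the fully
    expanded string over {H, P}.
    """

    residues: str
    source_notation: str | None = None

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError("HP sequence must contain at least one residue")
        bad = set(self.residues) - {"H", "P"}
        if bad:
            raise ValueError(f"invalid residue symbols: {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.residues)

    @property
    def n_h(self) -> int:
        return self.residues.count("H")

    def __len__(self) -> int:  # pragma: no cover - convenience
        return len(self.residues)

    def __str__(self) -> str:
        return self.residues


# ---------------------------------------------------------------------------
# Run-length notation
# ---------------------------------------------------------------------------

def _read_number(text: str, i: int) -> tuple[int, int]:
    j = i
    while j < len(text) and text[j].isdigit():
        j += 1
    value = int(text[i:j])
    if value < 1:
        raise HPNotationError("multiplier must be >= 1", i)
    return value, j


def _parse_prefix(text: str, i: int, depth: int) -> tuple[str, int]:
    """seq := ( [number] (symbol | '(' seq ')') )*"""
    out: list[str] = []
    while i < len(text):
        ch = text[i]
        if ch == ")":
            if depth == 0:
                raise HPNotationError("unbalanced ')'", i)
            return "".join(out), i
        mult = 1
        if ch.isdigit():
            mult, i = _read_number(text, i)
            if i >= len(text):
                raise HPNotationError("dangling multiplier", i - 1)
            ch = text[i]
        if ch in "HP":
            out.append(ch * mult)
            i += 1
        elif ch == "(":
            inner, j = _parse_prefix(text, i + 1, depth + 1)
            if j >= len(text) or text[j] != ")":
                raise HPNotationError("unbalanced '('", i)
            out.append(inner * mult)
            i = j + 1
        else:
            raise HPNotationError(f"unexpected character {ch!r}", i)
    return "".join(out), i


def _parse_caret(text: str, i: int, depth: int) -> tuple[str, int]:
    """seq := ( (symbol | '(' seq ')') ['^' number] )*"""
    out: list[str] = []
    while i < len(text):
        ch = text[i]
        if ch == ")":
            if depth == 0:
                raise HPNotationError("unbalanced ')'", i)
            return "".join(out), i
        if ch in "HP":
            unit = ch
            i += 1
        elif ch == "(":
            unit, j = _parse_caret(text, i + 1, depth + 1)
            if j >= len(text) or text[j] != ")":
                raise HPNotationError("unbalanced '('", i)
            i = j + 1
        else:
            raise HPNotationError(f"unexpected character {ch!r}", i)
        if i < len(text) and text[i] == "^":
            i += 1
            if i >= len(text) or not text[i].isdigit():
                raise HPNotationError("'^' must be followed by a number", i - 1)
            mult, i = _read_number(text, i)
            unit = unit * mult
        out.append(unit)
    return "".join(out), i


def parse_hp_notation(text: str, dialect: str = "auto") -> HPSequence:
    """Expand a run-length HP string into an :class:`HPSequence`.

    Parameters
    ----------
    text:
        Run-length notation over ``H P 0-9 ( ) ^`` (whitespace ignored).
        A plain HP string is a valid degenerate case of either dialect.
    dialect:
        ``"prefix"``, ``"caret"`` or ``"auto"`` (caret iff ``^`` occurs).
    """
    compact = "".join(text.split())
    if not compact:
        raise HPNotationError("empty notation", 0)
    if dialect == "auto":
        dialect = "caret" if "^" in compact else "prefix"
    if dialect == "prefix":
        if "^" in compact:
            raise HPNotationError("'^' not allowed in prefix dialect", compact.index("^"))
        residues, _ = _parse_prefix(compact, 0, 0)
    elif dialect == "caret":
        residues, _ = _parse_caret(compact, 0, 0)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    if not residues:
        raise HPNotationError("notation expands to an empty sequence", 0)
    return HPSequence(residues=residues, source_notation=text)


def compress_hp(seq: HPSequence | str, dialect: str = "prefix") -> str:
    """Greedy run-length compression of an expanded HP string.

    The inverse direction of :func:`parse_hp_notation` up to notation
    equivalence: expanding the result reproduces the residue string exactly.
    """
    residues = seq.residues if isinstance(seq, HPSequence) else seq
    parts: list[str] = []
    i = 0
    while i < len(residues):
        j = i
        while j < len(residues) and residues[j] == residues[i]:
            j += 1
        n = j - i
        if n == 1:
            parts.append(residues[i])
        elif dialect == "prefix":
            parts.append(f"{n}{residues[i]}")
        else:
            parts.append(f"{residues[i]}^{n}")
        i = j
    return "".join(parts)


# ---------------------------------------------------------------------------
# Amino-acid translation
# ---------------------------------------------------------------------------

def fasta_to_hp(amino_seq: str, override: dict[str, str] | None = None) -> HPSequence:
    """Translate a one-letter amino-acid sequence to its HP sequence.

    Each residue is mapped by class membership (see module docstring);
    ``override`` may remap individual amino acids to ``"H"`` or ``"P"``.
    Ambiguity codes (B, J, O, U, X, Z) are rejected with their positions.
    """
    mapping = {aa: "H" for aa in H_CLASS}
    mapping.update({aa: "P" for aa in P_CLASS})
    if override:
        for aa, hp in override.items():
            if hp not in ("H", "P"):
                raise ValueError(f"override for {aa!r} must be 'H' or 'P'")
            mapping[aa.upper()] = hp
    cleaned = "".join(amino_seq.split()).upper()
    bad = [i for i, aa in enumerate(cleaned) if aa not in mapping]
    if bad:
        codes = sorted({cleaned[i] for i in bad})
        raise ValueError(
            f"unsupported amino-acid codes {codes} at positions {bad}"
        )
    return HPSequence(
        residues="".join(mapping[aa] for aa in cleaned),
        source_notation=cleaned,
    )


def read_fasta(path: str | Path, record_id: str | None = None) -> str:
    """Return the amino-acid sequence of one record from a FASTA file.

    The first record is used unless ``record_id`` names another one.
    """
    from Bio import SeqIO

    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    if record_id is None:
        return str(records[0].seq)
    for rec in records:
        if rec.id == record_id:
            return str(rec.seq)
    raise KeyError(f"record {record_id!r} not found in {path}")


def hydrophobic_fraction(seq: HPSequence) -> float:
    """Hydrophobic percentage, 100 * n_h / L."""
    return 100.0 * seq.n_h / seq.length
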