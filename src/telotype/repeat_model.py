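"""Curated telomere repeat set and its one-character symbol alphabet.

Human telomeres are arrays of the canonical hexamer TTAGGG. The region
between the subtelomere and the pure telomere (the TVR region) additionally
contains *variant* repeats: canonical repeats modified by a single base
substitution (e.g. TCAGGG) or by insertion/deletion (e.g. TTAAGGG, TAGG).
Each repeat is assigned a one-character symbol drawn from the amino-acid
alphabet so that downstream clustering and consensus steps can reuse
standard sequence-alignment machinery on symbol strings.

Some table rows are *families*: several closely related sequences (all
derived from the canonical repeat by homopolymer indels) that share one
symbol. Matching operates on sequences; reporting operates on symbols.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Optional, Union

__all__ = [
    "RepeatDef",
    "RepeatSet",
    "RepeatSetError",
    "CANONICAL_SEQUENCE",
    "UNKNOWN_SYMBOL",
    "load_repeat_set",
    "reverse_complement_set",
    "reverse_complement",
]

CANONICAL_SEQUENCE = "TTAGGG"

#: Reserved symbol for unmatched base runs. "-" is kept for alignment gaps.
UNKNOWN_SYMBOL = "?"

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class RepeatSetError(ValueError):
    """Raised for an invalid repeat-set configuration."""


@dataclass(frozen=True)
class RepeatDef:
    """One telomere repeat sequence with its symbol and display metadata.

    ``canonical_indel_variant`` marks repeats that are the canonical repeat
    modified by a homopolymer insertion or deletion (the TAGG and TTGG
    families, the septamers). Isolated matches to these are the typical
    footprint of homopolymer sequencing errors and are eligible for
    singleton pruning; substitution-type variants never are.
    """

    sequence: str
    symbol: str
    category: str  # canonical | common | rare | error
    canonical_indel_variant: bool = False
    plot_color: str = "gray"

    def __post_init__(self) -> None:
        if len(self.sequence) < 4 or set(self.sequence) - set("ACGT"):
            raise RepeatSetError(
                f"repeat sequence must be >=4bp of ACGT, got {self.sequence!r}"
            )
        if len(self.symbol) != 1 or not self.symbol.isprintable():
            raise RepeatSetError(f"symbol must be one printable char, got {self.symbol!r}")
        if self.category not in ("canonical", "common", "rare", "error"):
            raise RepeatSetError(f"unknown category {self.category!r}")


# Default repeat table. Families sharing a symbol are expanded into separate
# sequence rows. The septamers TTAGGGG (TAGG family) and TTTAGGG (symbol Y)
# are included so that the common 7-mer variants are matchable.
_DEFAULT_ROWS = [
    # sequence, symbol, category, indel_variant, color
    ("TTAGGG", "C", "canonical", False, "blue"),
    ("TCAGGG", "D", "common", False, "red"),
    ("TGAGGG", "E", "common", False, "yellow"),
    ("TTGGGG", "F", "common", False, "green"),
    ("CGAGGG", "G", "common", False, "tan"),
    ("CTAGGG", "H", "common", False, "orange"),
    ("CTGGGG", "I", "common", False, "purple"),
    ("TAAGGG", "K", "common", False, "cyan"),
    ("TCCGGG", "L", "common", False, "pink"),
    ("TTCGGG", "M", "common", False, "violet"),
    ("CTAGG", "N", "rare", False, "darkorange"),
    ("TCGGG", "P", "rare", False, "darkviolet"),
    ("TGGGGG", "Q", "rare", False, "lightgreen"),
    ("TTAAGGG", "R", "rare", False, "darkcyan"),
    ("TTAGAGGG", "S", "rare", False, "gold"),
    ("TAGG", "T", "error", True, "darkblue"),
    ("TAGGG", "T", "error", True, "darkblue"),
    ("TAGGGG", "T", "error", True, "darkblue"),
    ("TTAGG", "T", "error", True, "darkblue"),
    ("TTAGGGG", "T", "error", True, "darkblue"),
    ("TTGG", "V", "error", True, "darkgreen"),
    ("TGGG", "V", "error", True, "darkgreen"),
    ("TTGGG", "V", "error", True, "darkgreen"),
    ("GGGGGG", "W", "error", False, "gray"),
    ("TTTAGGG", "Y", "error", True, "steelblue"),
]


class RepeatSet:
    """A validated, ordered collection of :class:`RepeatDef`.

    Order is meaningful: it is the tie-break priority used by the greedy
    longest-first matcher for repeats of equal length.
    """

    def __init__(self, repeats: Iterable[RepeatDef], unknown_symbol: str = UNKNOWN_SYMBOL):
        self.repeats: tuple[RepeatDef, ...] = tuple(repeats)
        self.unknown_symbol = unknown_symbol
        self._validate()
        self._by_sequence = {r.sequence: r for r in self.repeats}
        self._by_symbol: dict[str, list[RepeatDef]] = {}
        for r in self.repeats:
            self._by_symbol.setdefault(r.symbol, []).append(r)

    # -- validation -------------------------------------------------------
    def _validate(self) -> None:
        if not self.repeats:
            raise RepeatSetError("empty repeat set")
        seqs: dict[str, RepeatDef] = {}
        for r in self.repeats:
            if r.sequence in seqs:
                raise RepeatSetError(f"duplicate repeat sequence {r.sequence}")
            seqs[r.sequence] = r
        canon = [r for r in self.repeats if r.category == "canonical"]
        if len(canon) != 1:
            raise RepeatSetError(
                f"exactly one canonical repeat required, found {len(canon)}"
            )
        # symbols may be shared only within one family: identical symbol,
        # category, indel flag and color.
        by_symbol: dict[str, RepeatDef] = {}
        for r in self.repeats:
            if r.symbol == self.unknown_symbol or r.symbol == "-":
                raise RepeatSetError(
                    f"symbol {r.symbol!r} collides with a reserved character"
                )
            prev = by_symbol.get(r.symbol)
            if prev is not None:
                same_family = (
                    prev.category == r.category
                    and prev.canonical_indel_variant == r.canonical_indel_variant
                    and prev.plot_color == r.plot_color
                )
                if not same_family:
                    raise RepeatSetError(
                        f"symbol {r.symbol} shared by non-family entries "
                        f"{prev.sequence} and {r.sequence}"
                    )
            else:
                by_symbol[r.symbol] = r

    # -- lookups ----------------------------------------------------------
    @property
    def canonical(self) -> RepeatDef:
        return next(r for r in self.repeats if r.category == "canonical")

    @property
    def canonical_symbol(self) -> str:
        return self.canonical.symbol

    @property
    def symbols(self) -> tuple[str, ...]:
        """Distinct symbols in table order."""
        seen: list[str] = []
        for r in self.repeats:
            if r.symbol not in seen:
                seen.append(r.symbol)
        return tuple(seen)

    @property
    def alphabet(self) -> str:
        """All symbols plus the unknown symbol, as one string."""
        return "".join(self.symbols) + self.unknown_symbol

    def by_sequence(self, seq: str) -> RepeatDef:
        return self._by_sequence[seq]

    def family(self, symbol: str) -> list[RepeatDef]:
        return list(self._by_symbol[symbol])

    def decode_symbol(self, symbol: str) -> str:
        """Primary (first-listed) sequence for a symbol; 6 Ns for unknown."""
        if symbol == self.unknown_symbol:
            return "N" * 6
        return self._by_symbol[symbol][0].sequence

    def color(self, symbol: str) -> str:
        if symbol == self.unknown_symbol:
            return "lightgray"
        return self._by_symbol[symbol][0].plot_color

    def is_indel_variant(self, symbol: str) -> bool:
        if symbol == self.unknown_symbol:
            return False
        return self._by_symbol[symbol][0].canonical_indel_variant

    def __len__(self) -> int:
        return len(self.repeats)

    def __iter__(self):
        return iter(self.repeats)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, RepeatSet)
            and self.repeats == other.repeats
            and self.unknown_symbol == other.unknown_symbol
        )

    # -- serialization ----------------------------------------------------
    def to_tsv(self, path: Union[str, Path]) -> None:
        with open(path, "w") as fh:
            fh.write("sequence\tsymbol\tcategory\tindel_variant\tcolor\n")
            for r in self.repeats:
                fh.write(
                    f"{r.sequence}\t{r.symbol}\t{r.category}\t"
                    f"{int(r.canonical_indel_variant)}\t{r.plot_color}\n"
                )


def load_repeat_set(config_path: Optional[Union[str, Path]] = None) -> RepeatSet:
    """Load the repeat set from a TSV config, or the built-in default table.

    The TSV has a header row (sequence, symbol, category[, indel_variant,
    color]); "#" lines are comments. Family members are expressed as
    several rows sharing a symbol with identical metadata.
    """
    if config_path is None:
        return RepeatSet(RepeatDef(s, y, c, iv, col) for s, y, c, iv, col in _DEFAULT_ROWS)
    rows: list[RepeatDef] = []
    with open(config_path) as fh:
        header = None
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = [f.strip().lower() for f in fields]
                continue
            rec = dict(zip(header, fields))
            try:
                rows.append(
                    RepeatDef(
                        sequence=rec["sequence"].upper(),
                        symbol=rec["symbol"],
                        category=rec.get("category", "common"),
                        canonical_indel_variant=rec.get("indel_variant", "0")
                        in ("1", "true", "True"),
                        plot_color=rec.get("color", "gray"),
                    )
                )
            except KeyError as exc:
                raise RepeatSetError(f"missing column {exc} in {config_path}") from exc
    rs = RepeatSet(rows)
    if rs.canonical.sequence != CANONICAL_SEQUENCE:
        raise RepeatSetError(
            f"canonical repeat must be {CANONICAL_SEQUENCE}, got {rs.canonical.sequence}"
        )
    return rs


def reverse_complement_set(rs: RepeatSet) -> RepeatSet:
    """Reverse-complement every sequence, keeping symbols and metadata.

    Telomeres read from the C-strand appear as CCCTAA-family repeats; this
    produces the matching C-strand repeat set.
    """
    return RepeatSet(
        (replace(r, sequence=reverse_complement(r.sequence)) for r in rs.repeats),
        unknown_symbol=rs.unknown_symbol,
    )
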