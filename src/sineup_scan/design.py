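"""miniSINEUP construct design.

A miniSINEUP is the minimal synthetic form of a SINEUP: a binding domain
(BD) — the reverse complement of the target mRNA around its start codon —
joined by a spacer to an effector domain (ED), the embedded transposable
element (e.g. an inverted SINEB2, a FRAM or a MIRb). The default BD window
is -35/+4 relative to the A of the AUG (positions -1 and +1 are adjacent;
there is no 0), i.e. 39 nt. Deletion controls: a delta-ED construct keeps
BD + spacer only, a delta-BD construct keeps spacer + ED only.

Constructs are handled as DNA; U on input is mapped to T.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

from Bio.Seq import Seq

from sineup_scan.errors import CoordError, SequenceError, TargetError
from sineup_scan.models import RepeatFeature

_ALPHABET = set("ACGTN")


def _clean(seq: str, what: str = "sequence") -> str:
    """Uppercase, map U->T, and validate against the {A,C,G,T,N} alphabet."""
    s = seq.upper().replace("U", "T")
    bad = set(s) - _ALPHABET
    if bad:
        raise SequenceError(f"{what} contains invalid characters {sorted(bad)}")
    return s


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N self-complements)."""
    return str(Seq(_clean(seq)).reverse_complement())


@dataclass
class SineupConstruct:
    """A designed (mini)SINEUP sequence: BD + spacer + ED, 5'->3'."""

    name: str
    bd_seq: str
    spacer_seq: str
    ed_seq: str
    target_id: str = ""
    bd_window_used: tuple[int, int] = (35, 4)

    def __post_init__(self):
        self.bd_seq = _clean(self.bd_seq, "BD") if self.bd_seq else ""
        self.spacer_seq = _clean(self.spacer_seq, "spacer") if self.spacer_seq else ""
        self.ed_seq = _clean(self.ed_seq, "ED") if self.ed_seq else ""

    @property
    def full_seq(self) -> str:
        return self.bd_seq + self.spacer_seq + self.ed_seq

    @property
    def element_coords(self) -> dict[str, tuple[int, int]]:
        """[start, end) of each element within full_seq, in order BD, spacer, ED."""
        b, s = len(self.bd_seq), len(self.spacer_seq)
        return {
            "BD": (0, b),
            "spacer": (b, b + s),
            "ED": (b + s, len(self.full_seq)),
        }


def design_bd(
    mrna_seq: str, atg_index: int, up: int = 35, down: int = 4
) -> str:
    """Design a binding domain against an mRNA around its start codon.

    Returns the reverse complement of ``mrna_seq[atg_index-up : atg_index+down]``.
    ``atg_index`` is the 0-based position of the A of the AUG; the default
    -35/+4 window yields a 39-nt BD. When fewer than ``up`` nucleotides
    precede the AUG the window truncates at the 5' end with a warning.
    """
    mrna = _clean(mrna_seq, "mRNA")
    if atg_index < 0 or mrna[atg_index : atg_index + 3] != "ATG":
        raise TargetError(f"no ATG at position {atg_index}")
    if atg_index + down > len(mrna):
        raise TargetError(
            f"window +{down} past the end of the mRNA ({len(mrna)} nt)"
        )
    lo = atg_index - up
    if lo < 0:
        warnings.warn(
            f"only {atg_index} nt precede the AUG; BD truncated to "
            f"-{atg_index}/+{down}",
            stacklevel=2,
        )
        lo = 0
    return revcomp(mrna[lo : atg_index + down])


def extract_ed(
    genome_seq: Mapping[str, str],
    repeat: RepeatFeature,
    nat_strand: str = "+",
    invert: bool = False,
) -> str:
    """Extract an effector-domain sequence as it appears in the antisense RNA.

    ``genome_seq`` maps chromosome name to sequence (plus strand). The repeat
    substring is returned as transcribed in the NAT: reverse-complemented when
    the repeat's annotated strand opposes ``nat_strand`` (the inverted-element
    case), verbatim otherwise. ``invert`` flips the rule.
    """
    if repeat.chrom not in genome_seq:
        raise CoordError(f"chromosome {repeat.chrom!r} not in the provided sequences")
    chrom_seq = genome_seq[repeat.chrom]
    iv = repeat.interval
    if iv.end > len(chrom_seq):
        raise CoordError(
            f"repeat [{iv.start}, {iv.end}) outside {repeat.chrom} "
            f"({len(chrom_seq)} nt)"
        )
    sub = _clean(chrom_seq[iv.start : iv.end], "ED")
    flip = repeat.strand != nat_strand
    if invert:
        flip = not flip
    return revcomp(sub) if flip else sub


#: Shipped neutral 20-nt spacer used when no spacer file is supplied.
DEFAULT_SPACER = "GCTAGCACGCGTACTAGTCG"


def assemble_minisineup(
    bd: str,
    spacer: str,
    ed: str,
    name: str,
    target_id: str = "",
    bd_window_used: tuple[int, int] = (35, 4),
) -> SineupConstruct:
    """Concatenate BD + spacer + ED into a construct (any element may be empty)."""
    return SineupConstruct(
        name=name,
        bd_seq=bd,
        spacer_seq=spacer,
        ed_seq=ed,
        target_id=target_id,
        bd_window_used=bd_window_used,
    )


def make_delta_ed(c: SineupConstruct) -> SineupConstruct:
    """Effector-deletion control: BD + spacer, no ED."""
    return SineupConstruct(
        name=f"{c.name}_deltaED",
        bd_seq=c.bd_seq,
        spacer_seq=c.spacer_seq,
        ed_seq="",
        target_id=c.target_id,
        bd_window_used=c.bd_window_used,
    )


def make_delta_bd(c: SineupConstruct) -> SineupConstruct:
    """Binding-deletion control: spacer + ED, no BD (no target overlap)."""
    return SineupConstruct(
        name=f"{c.name}_deltaBD",
        bd_seq="",
        spacer_seq=c.spacer_seq,
        ed_seq=c.ed_seq,
        target_id=c.target_id,
        bd_window_used=c.bd_window_used,
    )


def emit_construct(
    c: SineupConstruct, fasta_path: str | Path, table_path: str | Path | None = None
) -> None:
    """Write the construct as FASTA (60-column wrap) plus an element table.

    The table lists each element's coordinates within the construct,
    1-based closed, as labelled.
    """
    from sineup_scan.io import write_fasta

    write_fasta({c.name: c.full_seq}, fasta_path)
    if table_path is None:
        table_path = str(Path(fasta_path).with_suffix(".elements.tsv"))
    with open(table_path, "w") as fh:
        fh.write("construct\telement\tstart_1based\tend_1based\tlength\n")
        for element, (s, e) in c.element_coords.items():
            if e > s:
                fh.write(f"{c.name}\t{element}\t{s + 1}\t{e}\t{e - s}\n")
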