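"""The pentamer library: enumeration, context and motif matching.

A complete saturation-mutagenesis library replaces one 5-nt window of an
intron with every possible RNA pentamer (4^5 = 1024 words, including the
wild type).  The window sits in a fixed sequence context, so a motif can be
formed partly by the invariant flanks and partly by the variable pentamer —
matching therefore supports both pentamer-internal and flank-aware searches.

Coordinates: pentamer positions are 1..5 (1-based).  Upstream flank bases
are numbered −1, −2, ... counting away from the pentamer (the base
immediately 5' of position 1 is −1); downstream flank bases are 6, 7, ...
There is no position 0.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Sequence

RNA_ALPHABET = "ACGU"

#: IUPAC degenerate nucleotide codes, on the RNA alphabet.
IUPAC = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "U": frozenset("U"),
    "N": frozenset("ACGU"),
    "Y": frozenset("CU"),
    "R": frozenset("AG"),
    "W": frozenset("AU"),
    "S": frozenset("CG"),
    "K": frozenset("GU"),
    "M": frozenset("AC"),
    "B": frozenset("CGU"),
    "D": frozenset("AGU"),
    "H": frozenset("ACU"),
    "V": frozenset("ACG"),
}

_ANCHORS = ("anywhere", "pos1", "pos2", "pos3")


def normalize_rna(seq: str) -> str:
    """Uppercase and convert DNA T to RNA U."""
    return seq.strip().upper().replace("T", "U")


def validate_pentamer(seq: str) -> str:
    """Normalize *seq* and check it is a valid 5-nt RNA word."""
    s = normalize_rna(seq)
    if len(s) != 5:
        raise ValueError(f"pentamer must have length 5, got {seq!r}")
    bad = set(s) - set(RNA_ALPHABET)
    if bad:
        raise ValueError(f"pentamer {seq!r} contains non-RNA characters {sorted(bad)}")
    return s


@dataclass(frozen=True)
class LibraryContext:
    """Fixed sequence context of the mutagenized pentamer window.

    Defaults describe the SMN2 intron-7 library: the wild-type pentamer
    CAGCA occupies intron positions +11..+15, the upstream flank ends in
    UGC and the downstream flank begins with UUAU.
    """

    upstream_flank: str = "UGC"
    downstream_flank: str = "UUAU"
    wt_pentamer: str = "CAGCA"
    intron_offset: int = 11

    def __post_init__(self):
        object.__setattr__(self, "upstream_flank", normalize_rna(self.upstream_flank))
        object.__setattr__(self, "downstream_flank", normalize_rna(self.downstream_flank))
        object.__setattr__(self, "wt_pentamer", validate_pentamer(self.wt_pentamer))
        for name, s in (("upstream_flank", self.upstream_flank),
                        ("downstream_flank", self.downstream_flank)):
            bad = set(s) - set(RNA_ALPHABET)
            if bad:
                raise ValueError(f"{name} contains non-RNA characters {sorted(bad)}")
        if len(self.upstream_flank) < 3:
            raise ValueError("upstream_flank must be at least 3 nt")
        if len(self.downstream_flank) < 4:
            raise ValueError("downstream_flank must be at least 4 nt")

    def context_string(self, pentamer: str) -> str:
        """The pentamer embedded in its flanks."""
        return self.upstream_flank + validate_pentamer(pentamer) + self.downstream_flank


@dataclass(frozen=True)
class MotifPattern:
    """A degenerate RNA motif with optional positional anchoring.

    ``anchor`` is ``"anywhere"`` or ``"posK"`` (K in 1..3), in which case the
    pattern is a 3-mer matched starting at pentamer position K.
    ``use_flanks`` widens the search window to flank+pentamer+flank; a
    flank-aware match must still overlap the pentamer by at least 1 nt.
    """

    pattern: str
    anchor: str = "anywhere"
    use_flanks: bool = False

    def __post_init__(self):
        object.__setattr__(self, "pattern", normalize_rna(self.pattern))
        if not self.pattern:
            raise ValueError("empty motif pattern")
        bad = set(self.pattern) - set(IUPAC)
        if bad:
            raise ValueError(f"pattern {self.pattern!r} has unknown codes {sorted(bad)}")
        if self.anchor not in _ANCHORS:
            raise ValueError(f"anchor must be one of {_ANCHORS}, got {self.anchor!r}")
        if self.anchor != "anywhere" and len(self.pattern) != 3:
            raise ValueError("positionally anchored patterns must be 3-mers")

    @property
    def anchor_pos(self) -> int | None:
        return None if self.anchor == "anywhere" else int(self.anchor[3:])


def enumerate_library(context: LibraryContext | None = None) -> list[str]:
    """All 4^5 = 1024 pentamers in lexicographic order (A < C < G < U)."""
    return ["".join(p) for p in itertools.product(RNA_ALPHABET, repeat=5)]


def _site_matches(window: str, pattern: str) -> bool:
    return all(window[i] in IUPAC[c] for i, c in enumerate(pattern))


def match(pentamer: str, motif: MotifPattern, ctx: LibraryContext | None = None,
          ) -> tuple[bool, list[int]]:
    """Match *motif* against *pentamer* (optionally flank-aware).

    Returns ``(matched, offsets)`` where offsets are 1-based start positions
    relative to the pentamer (upstream flank offsets are negative, counted
    from −1 immediately 5' of the pentamer; downstream offsets are > 5).
    Flank-aware matches must overlap the pentamer by at least one base.
    """
    p = validate_pentamer(pentamer)
    pat = motif.pattern
    if motif.use_flanks:
        if ctx is None:
            raise ValueError("flank-aware matching requires a LibraryContext")
        search = ctx.upstream_flank + p + ctx.downstream_flank
        up = len(ctx.upstream_flank)
    else:
        search = p
        up = 0
    if len(pat) > len(search):
        raise ValueError(
            f"pattern {pat!r} longer than the {len(search)}-nt search window")

    offsets: list[int] = []
    if motif.anchor_pos is not None:
        k = motif.anchor_pos
        start0 = up + (k - 1)
        if start0 + len(pat) <= len(search) and _site_matches(search[start0:start0 + len(pat)], pat):
            offsets.append(k)
    else:
        for start0 in range(len(search) - len(pat) + 1):
            lo = start0 - up          # 0-based offset of window start wrt pentamer pos 1
            hi = lo + len(pat) - 1    # 0-based offset of window end
            if hi < 0 or lo > 4:      # window must overlap the pentamer
                continue
            if _site_matches(search[start0:start0 + len(pat)], pat):
                # convert 0-based offset to the 1-based coordinate scheme
                # (no position 0: upstream bases are −1, −2, ...)
                offsets.append(lo + 1 if lo >= 0 else lo)
    return bool(offsets), offsets


def count_matching(patterns: MotifPattern | Iterable[MotifPattern],
                   ctx: LibraryContext | None = None) -> int:
    """Number of distinct library pentamers matching at least one pattern."""
    if isinstance(patterns, MotifPattern):
        patterns = [patterns]
    patterns = list(patterns)
    if not patterns:
        raise ValueError("at least one pattern is required")
    n = 0
    for p in enumerate_library(ctx):
        if any(match(p, m, ctx)[0] for m in patterns):
            n += 1
    return n


def matching_pentamers(patterns: MotifPattern | Iterable[MotifPattern],
                       ctx: LibraryContext | None = None) -> list[str]:
    """Library pentamers (lexicographic order) matching at least one pattern."""
    if isinstance(patterns, MotifPattern):
        patterns = [patterns]
    patterns = list(patterns)
    return [p for p in enumerate_library(ctx)
            if any(match(p, m, ctx)[0] for m in patterns)]


def repeat_count(pentamer: str, unit: str) -> int:
    """Occurrences of a 1- or 2-nt repeat unit in a pentamer.

    Single bases are counted everywhere; dinucleotides are counted as
    maximal non-overlapping occurrences by a greedy left-to-right scan
    (AUUUU contains UU twice; AGAGA contains AG twice).
    """
    p = validate_pentamer(pentamer)
    u = normalize_rna(unit)
    if len(u) not in (1, 2) or set(u) - set(RNA_ALPHABET):
        raise ValueError(f"repeat unit must be 1 or 2 RNA bases, got {unit!r}")
    if len(u) == 1:
        return p.count(u)
    n = 0
    i = 0
    while i <= len(p) - 2:
        if p[i:i + 2] == u:
            n += 1
            i += 2
        else:
            i += 1
    return n


def write_pentamer_list(pentamers: Sequence[str], path) -> None:
    with open(path, "w") as fh:
        for p in pentamers:
            fh.write(validate_pentamer(p) + "\n")


def read_pentamer_list(path) -> list[str]:
    with open(path) as fh:
        return [validate_pentamer(line) for line in fh if line.strip()]


def write_context_fasta(pentamers: Sequence[str], ctx: LibraryContext, path) -> None:
    """FASTA export of flank+pentamer+flank context strings."""
    with open(path, "w") as fh:
        for p in pentamers:
            p = validate_pentamer(p)
            fh.write(f">pentamer_{p}\n{ctx.context_string(p)}\n")
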