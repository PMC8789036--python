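"""Six-layer motif-set construction over the pentamer library, with GMT IO.

A motif set groups pentamers sharing one sequence feature.  Six layers of
features describe a pentamer:

* ``non_positional`` — contains a given 3-mer (64 sets) or 4-mer (256 sets)
  anywhere in the 5-nt word;
* ``pos1`` / ``pos2`` / ``pos3`` — carries a given 3-mer anchored at
  pentamer positions 1–3, 2–4, or 3–5 (64 sets each);
* ``repeat`` — repeats a single base at least c times (c = 2..5, named
  ``U:U``, ``U:U:U``, ...) or a dinucleotide at least twice without overlap
  (named ``AG:AG``);
* ``interaction`` — has a given base pair at a given ordered position pair
  (10 position pairs × 16 base pairs, named with dots, e.g. ``A.U..`` for
  A at position 1 and U at position 3).

Sets outside a size band (default [7, 200] members) are removed before
scoring to avoid degenerate enrichment statistics.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from .library import (
    RNA_ALPHABET,
    LibraryContext,
    enumerate_library,
    normalize_rna,
    repeat_count,
    validate_pentamer,
)

LAYERS = ("non_positional", "pos1", "pos2", "pos3", "repeat", "interaction")

DEFAULT_MIN_SIZE = 7
DEFAULT_MAX_SIZE = 200


@dataclass(frozen=True)
class MotifSet:
    """A named group of pentamers sharing one sequence feature."""

    set_id: str
    layer: str
    members: tuple[str, ...]
    description: str = ""

    def __post_init__(self):
        if self.layer not in LAYERS:
            raise ValueError(f"unknown layer {self.layer!r}")
        members = tuple(validate_pentamer(m) for m in self.members)
        if len(set(members)) != len(members):
            raise ValueError(f"motif set {self.set_id} has duplicate members")
        object.__setattr__(self, "members", members)

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class MotifSetCollection:
    """An ordered collection of motif sets plus its generation parameters."""

    sets: list[MotifSet]
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        ids = [s.set_id for s in self.sets]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate set ids: {dup[:5]}")

    def __len__(self):
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def by_id(self) -> dict[str, MotifSet]:
        return {s.set_id: s for s in self.sets}

    def by_layer(self, layer: str) -> list[MotifSet]:
        return [s for s in self.sets if s.layer == layer]

    def sizes(self) -> dict[str, int]:
        return {s.set_id: s.size for s in self.sets}


def _kmers(k: int) -> list[str]:
    return ["".join(t) for t in itertools.product(RNA_ALPHABET, repeat=k)]


def generate_layer(layer: str, library: list[str] | None = None,
                   ctx: LibraryContext | None = None) -> list[MotifSet]:
    """Generate every motif set of one layer over the library.

    Membership is pentamer-internal (flanks play no role in set
    construction; flank-completed motifs are the classifier's job).
    """
    library = library if library is not None else enumerate_library(ctx)
    sets: list[MotifSet] = []

    if layer == "non_positional":
        for k in (3, 4):
            for kmer in _kmers(k):
                members = tuple(p for p in library if kmer in p)
                sets.append(MotifSet(kmer, layer, members,
                                     f"pentamers containing {kmer} at any position"))
    elif layer in ("pos1", "pos2", "pos3"):
        k = int(layer[3:])
        for kmer in _kmers(3):
            word = "N" * (k - 1) + kmer + "N" * (3 - k)
            members = tuple(p for p in library if p[k - 1:k + 2] == kmer)
            sets.append(MotifSet(f"{word}@{layer}", layer, members,
                                 f"pentamers with {kmer} at positions {k}-{k + 2}"))
    elif layer == "repeat":
        for base in RNA_ALPHABET:
            for c in range(2, 6):
                set_id = ":".join([base] * c)
                members = tuple(p for p in library if repeat_count(p, base) >= c)
                sets.append(MotifSet(set_id, layer, members,
                                     f"pentamers with at least {c} copies of {base}"))
        for dinuc in _kmers(2):
            set_id = f"{dinuc}:{dinuc}"
            members = tuple(p for p in library if repeat_count(p, dinuc) >= 2)
            sets.append(MotifSet(set_id, layer, members,
                                 f"pentamers with {dinuc} repeated at least twice "
                                 "(non-overlapping)"))
    elif layer == "interaction":
        for i, j in itertools.combinations(range(5), 2):
            for a, b in itertools.product(RNA_ALPHABET, repeat=2):
                chars = ["."] * 5
                chars[i], chars[j] = a, b
                set_id = "".join(chars)
                members = tuple(p for p in library if p[i] == a and p[j] == b)
                sets.append(MotifSet(
                    set_id, layer, members,
                    f"pentamers with {a} at position {i + 1} and {b} at position {j + 1}"))
    else:
        raise ValueError(f"unknown layer {layer!r}")
    return sets


def generate_all_layers(layers: tuple[str, ...] = LAYERS,
                        ctx: LibraryContext | None = None) -> MotifSetCollection:
    library = enumerate_library(ctx)
    sets: list[MotifSet] = []
    for layer in layers:
        sets.extend(generate_layer(layer, library, ctx))
    return MotifSetCollection(sets, params={"layers": list(layers)})


def filter_sets(collection: MotifSetCollection,
                min_size: int = DEFAULT_MIN_SIZE,
                max_size: int = DEFAULT_MAX_SIZE,
                ) -> tuple[MotifSetCollection, list[MotifSet]]:
    """Keep sets with min_size <= size <= max_size; return (kept, removed)."""
    kept = [s for s in collection if min_size <= s.size <= max_size]
    removed = [s for s in collection if not (min_size <= s.size <= max_size)]
    params = dict(collection.params, min_size=min_size, max_size=max_size)
    return MotifSetCollection(kept, params=params), removed


def write_gmt(collection: MotifSetCollection, path) -> None:
    """GMT: one set per line — name, description, then members, tab-separated.

    The layer is carried in the description field as ``layer=<tag>; ...`` so
    the file round-trips losslessly.
    """
    with open(path, "w") as fh:
        for s in collection:
            desc = f"layer={s.layer}; {s.description}".rstrip("; ")
            fh.write("\t".join([s.set_id, desc, *s.members]) + "\n")


def read_gmt(path) -> MotifSetCollection:
    sets: list[MotifSet] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{ln}: GMT line needs a name, a description and "
                    "at least one member")
            set_id, desc = fields[0], fields[1]
            layer = "non_positional"
            if desc.startswith("layer="):
                layer, _, desc = desc.partition("; ")
                layer = layer.removeprefix("layer=")
            members = tuple(validate_pentamer(normalize_rna(m))
                            for m in fields[2:] if m.strip())
            if not members:
                raise ValueError(f"{path}:{ln}: motif set {set_id} has no members")
            sets.append(MotifSet(set_id, layer, members, desc))
    return MotifSetCollection(sets)


def write_set_sizes_tsv(collection: MotifSetCollection, path) -> None:
    with open(path, "w") as fh:
        fh.write("set_id\tlayer\tsize\n")
        for s in collection:
            fh.write(f"{s.set_id}\t{s.layer}\t{s.size}\n")
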