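"""Rule-based, flank-aware classification of splicing-regulatory motifs.

Enriched motifs fall into recurring SRE families.  Stimulatory (enhancer)
classes, tested in order:

* **CG-core** — contains the CG dinucleotide;
* **C-rich** — at least two Cs and more Cs than Us;
* **U-rich** — at least two Us; A/U-only motifs with a single U (e.g. AAU)
  also qualify because they extend the downstream UUAU into a UA-rich run;
* **RBFOX-related** — completes the RBFOX site UGCAUG with the upstream
  flank (...UGC + AUG...).

Inhibitory (silencer) classes are multi-label; all matches are reported
with the primary label first (precedence GCWCC-type > GAC-core > AG-core >
UG-type, so e.g. AGAC is primarily GAC-core while also AG-core):

* **AG-core** — contains AG, the core of hnRNP A1-type silencers;
* **UG-type** — contains UGG or GGU;
* **GAC-core** — contains GAC not immediately preceded by C (a preceding C,
  including the flank C when the motif is anchored at position 1,
  neutralizes the silencer);
* **GCWCC-type** — reconstitutes the potent silencer GCACC or GCUCC
  (W = A/U), either with the upstream ...GC flank or inside the pentamer.

Motifs matching no rule are ``unclassified``.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import pandas as pd
import yaml

from .library import LibraryContext, normalize_rna, validate_pentamer

STIMULATORY = "stimulatory"
INHIBITORY = "inhibitory"
UNCLASSIFIED = "unclassified"

CLASS_LABELS = ("U-rich", "C-rich", "CG-core", "RBFOX-related",
                "AG-core", "UG-type", "GAC-core", "GCWCC-type", UNCLASSIFIED)

_POS_ANCHORS = ("pos1", "pos2", "pos3")


@dataclass(frozen=True)
class ClassRuleSet:
    """Tunable parameters of the SRE classification rules."""

    cg_core: str = "CG"
    c_rich_min_c: int = 2
    u_rich_min_u: int = 2
    rbfox_site: str = "UGCAUG"
    ag_core: str = "AG"
    ug_type: tuple[str, ...] = ("UGG", "GGU")
    gac_core: str = "GAC"
    gac_neutralizing_preceding: str = "C"
    gcwcc_targets: tuple[str, ...] = ("GCACC", "GCUCC")
    gcwcc_min_len: int = 3

    def to_yaml(self) -> str:
        d = {k: list(v) if isinstance(v, tuple) else v
             for k, v in asdict(self).items()}
        return yaml.safe_dump(d, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "ClassRuleSet":
        d = yaml.safe_load(text)
        for k in ("ug_type", "gcwcc_targets"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


DEFAULT_RULES = ClassRuleSet()


@dataclass(frozen=True)
class MotifClassAssignment:
    """Classification of one motif: all labels (primary first) plus the
    matched-pattern evidence, including flank-completed sequences."""

    motif: str
    direction: str
    labels: tuple[str, ...]
    evidence: tuple[str, ...] = ()

    @property
    def primary(self) -> str:
        return self.labels[0]


def _anchor_allows_pos(anchor: str | None, pos: int) -> bool:
    """Whether the motif may start at pentamer position *pos* (1-based)."""
    if anchor in (None, "anywhere"):
        return True
    return anchor == f"pos{pos}"


def _rbfox_evidence(m: str, anchor: str | None, ctx: LibraryContext,
                    rules: ClassRuleSet) -> str | None:
    site = rules.rbfox_site
    if site in m:
        return f"contains {site}"
    if _anchor_allows_pos(anchor, 1):
        s = ctx.upstream_flank + m
        idx = s.find(site)
        if idx != -1 and idx + len(site) > len(ctx.upstream_flank):
            flank_part = ctx.upstream_flank[idx:]
            return (f"upstream flank ...{flank_part} + {m} completes {site}")
    return None


def _gcwcc_evidence(m: str, anchor: str | None, ctx: LibraryContext,
                    rules: ClassRuleSet) -> str | None:
    if len(m) < rules.gcwcc_min_len:
        return None
    for target in rules.gcwcc_targets:
        if not target.endswith(m):
            continue
        prefix = target[:-len(m)]
        if (_anchor_allows_pos(anchor, 1)
                and ctx.upstream_flank.endswith(prefix)):
            if prefix:
                return f"upstream flank ...{prefix} + {m} reconstitutes {target}"
            return f"motif is the full silencer {target}"
        if len(target) <= 5 and _anchor_allows_pos(anchor, len(prefix) + 1):
            return f"{m} completes {target} within the pentamer"
    return None


def _gac_evidence(m: str, anchor: str | None, ctx: LibraryContext,
                  rules: ClassRuleSet) -> str | None:
    core = rules.gac_core
    neutral = rules.gac_neutralizing_preceding
    start = 0
    while (idx := m.find(core, start)) != -1:
        start = idx + 1
        if idx > 0:
            prev: str | None = m[idx - 1]
        elif anchor == "pos1":
            prev = ctx.upstream_flank[-1]   # flank base immediately 5'
        else:
            prev = None                      # unknown pentamer base
        if prev == neutral:
            continue                         # C-preceded GAC is neutralized
        where = "unknown (not assumed C)" if prev is None else prev
        return f"contains {core} preceded by {where}"
    return None


def classify_motif(motif: str, direction: str,
                   ctx: LibraryContext | None = None,
                   anchor: str | None = None,
                   rules: ClassRuleSet = DEFAULT_RULES) -> MotifClassAssignment:
    """Classify a 2–6-nt motif into its SRE class(es).

    ``anchor`` restricts where the motif sits in the pentamer ("pos1".."pos3"
    per positional MSEA layers; None/"anywhere" otherwise), which controls
    the flank-aware rules (RBFOX completion, GCWCC reconstitution, the
    neutralizing C before GAC).
    """
    m = normalize_rna(motif)
    if not (2 <= len(m) <= 6) or set(m) - set("ACGU"):
        raise ValueError(f"motif must be 2-6 RNA bases, got {motif!r}")
    if direction not in (STIMULATORY, INHIBITORY):
        raise ValueError(
            f"direction must be {STIMULATORY!r} or {INHIBITORY!r}, got {direction!r}")
    ctx = ctx or LibraryContext()

    labels: list[str] = []
    evidence: list[str] = []
    if direction == STIMULATORY:
        n_c, n_u = m.count("C"), m.count("U")
        if rules.cg_core in m:
            labels, evidence = ["CG-core"], [f"contains {rules.cg_core}"]
        elif n_c >= rules.c_rich_min_c and n_c > n_u:
            labels, evidence = ["C-rich"], [f"{n_c} Cs > {n_u} Us"]
        elif n_u >= rules.u_rich_min_u:
            labels, evidence = ["U-rich"], [f"contains {n_u} Us"]
        elif set(m) <= set("AU") and "U" in m:
            labels = ["U-rich"]
            evidence = [f"A/U-only motif forms a UA-rich enhancer with the "
                        f"downstream {ctx.downstream_flank[:4]}"]
        elif (ev := _rbfox_evidence(m, anchor, ctx, rules)) is not None:
            labels, evidence = ["RBFOX-related"], [ev]
    else:
        if (ev := _gcwcc_evidence(m, anchor, ctx, rules)) is not None:
            labels.append("GCWCC-type")
            evidence.append(ev)
        if (ev := _gac_evidence(m, anchor, ctx, rules)) is not None:
            labels.append("GAC-core")
            evidence.append(ev)
        if rules.ag_core in m:
            labels.append("AG-core")
            evidence.append(f"contains {rules.ag_core}")
        if any(t in m for t in rules.ug_type):
            hit = next(t for t in rules.ug_type if t in m)
            labels.append("UG-type")
            evidence.append(f"contains {hit}")

    if not labels:
        labels, evidence = [UNCLASSIFIED], []
    return MotifClassAssignment(m, direction, tuple(labels), tuple(evidence))


def annotate_pentamer(pentamer: str, ctx: LibraryContext | None = None,
                      rules: ClassRuleSet = DEFAULT_RULES
                      ) -> list[tuple[int, str, MotifClassAssignment]]:
    """Scan all 2–6-nt windows overlapping the pentamer (flank-aware) and
    report every class match.

    Returns ``(offset, window, assignment)`` tuples ordered by offset then
    label, where offset is the window start in pentamer coordinates
    (upstream flank bases are −1, −2, ...; no position 0).
    """
    p = validate_pentamer(pentamer)
    ctx = ctx or LibraryContext()
    context = ctx.upstream_flank + p + ctx.downstream_flank
    up = len(ctx.upstream_flank)
    out = []
    for length in range(2, 7):
        for start0 in range(len(context) - length + 1):
            lo = start0 - up
            hi = lo + length - 1
            if hi < 0 or lo > 4:        # must overlap the pentamer
                continue
            window = context[start0:start0 + length]
            prev = context[start0 - 1] if start0 > 0 else None
            offset = lo + 1 if lo >= 0 else lo
            for a in _window_assignments(window, prev, ctx, rules):
                out.append((offset, window, a))
    out.sort(key=lambda t: (t[0], t[2].primary, len(t[1]), t[1]))
    return out


def _window_assignments(window: str, prev: str | None, ctx: LibraryContext,
                        rules: ClassRuleSet) -> list[MotifClassAssignment]:
    """Class matches of one concrete context window (both directions).

    Unlike :func:`classify_motif`, the window's neighborhood is fully known:
    flank bases are part of the window or of ``prev``, so flank-completion
    rules reduce to substring checks.
    """
    found: list[MotifClassAssignment] = []
    n_c, n_u = window.count("C"), window.count("U")
    # a window carrying the complete RBFOX site is definitively RBFOX,
    # whatever else it contains
    if rules.rbfox_site in window:
        found.append(MotifClassAssignment(
            window, STIMULATORY, ("RBFOX-related",),
            (f"contains {rules.rbfox_site}",)))
    elif rules.cg_core in window:
        found.append(MotifClassAssignment(
            window, STIMULATORY, ("CG-core",), (f"contains {rules.cg_core}",)))
    elif n_c >= rules.c_rich_min_c and n_c > n_u:
        found.append(MotifClassAssignment(
            window, STIMULATORY, ("C-rich",), (f"{n_c} Cs > {n_u} Us",)))
    elif n_u >= rules.u_rich_min_u:
        found.append(MotifClassAssignment(
            window, STIMULATORY, ("U-rich",), (f"contains {n_u} Us",)))

    labels: list[str] = []
    evidence: list[str] = []
    if any(t in window for t in rules.gcwcc_targets):
        hit = next(t for t in rules.gcwcc_targets if t in window)
        labels.append("GCWCC-type")
        evidence.append(f"contains {hit}")
    start = 0
    while (idx := window.find(rules.gac_core, start)) != -1:
        start = idx + 1
        p_char = window[idx - 1] if idx > 0 else prev
        if p_char != rules.gac_neutralizing_preceding:
            labels.append("GAC-core")
            evidence.append(f"contains {rules.gac_core} preceded by {p_char}")
            break
    if rules.ag_core in window:
        labels.append("AG-core")
        evidence.append(f"contains {rules.ag_core}")
    if any(t in window for t in rules.ug_type):
        hit = next(t for t in rules.ug_type if t in window)
        labels.append("UG-type")
        evidence.append(f"contains {hit}")
    if labels:
        found.append(MotifClassAssignment(
            window, INHIBITORY, tuple(labels), tuple(evidence)))
    return found


def decode_set_id(set_id: str) -> tuple[str | None, str | None]:
    """Decode a motif-set id to (motif, anchor); (None, None) if the set has
    no contiguous motif (nucleotide-interaction patterns)."""
    if "." in set_id:
        return None, None
    if "@" in set_id:
        word, _, anchor = set_id.partition("@")
        motif = word.strip("N")
        if not motif or "N" in motif:
            return None, None
        return motif, anchor
    if ":" in set_id:
        return "".join(set_id.split(":")), None
    return set_id, None


def classify_enriched_table(results: pd.DataFrame,
                            ctx: LibraryContext | None = None,
                            rules: ClassRuleSet = DEFAULT_RULES,
                            significant_only: bool = True) -> pd.DataFrame:
    """Classify enriched motif sets; direction comes from the NES sign
    (positive = stimulatory, negative = inhibitory).

    Sets whose id does not decode to a contiguous motif (interaction
    patterns) are flagged ``decoded=False`` and left unclassified.
    """
    ctx = ctx or LibraryContext()
    table = results[results["significant"]] if significant_only else results
    rows = []
    for _, r in table.iterrows():
        direction = STIMULATORY if r["nes"] >= 0 else INHIBITORY
        motif, anchor = decode_set_id(r["set_id"])
        if motif is None:
            rows.append({"set_id": r["set_id"], "layer": r["layer"],
                         "nes": r["nes"], "direction": direction,
                         "decoded": False, "primary_class": UNCLASSIFIED,
                         "all_classes": UNCLASSIFIED, "evidence": ""})
            continue
        a = classify_motif(motif, direction, ctx, anchor, rules)
        rows.append({"set_id": r["set_id"], "layer": r["layer"],
                     "nes": r["nes"], "direction": direction, "decoded": True,
                     "primary_class": a.primary,
                     "all_classes": ";".join(a.labels),
                     "evidence": "; ".join(a.evidence)})
    return pd.DataFrame(rows, columns=["set_id", "layer", "nes", "direction",
                                       "decoded", "primary_class",
                                       "all_classes", "evidence"])
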