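"""Synthetic replicate PSI matrices with planted motif effects.

The generator emulates the saturation-mutagenesis screen: every pentamer
gets a true inclusion level built from a baseline PSI (default 41%, the
basal exon-7 inclusion of the assayed minigene) plus additive planted
motif effects on the log-odds scale,

    PSI_true(p) = 100 · expit( logit(baseline/100) + Σ_{m matches p} effect_m ),

so effects compose additively in logits and saturate naturally near 0 and
100%.  Each replicate observation adds Gaussian measurement noise
(default sd 3 percentage points, comparable to the screen's replicate
differences) truncated to [0, 100].  WT control rows broadcast one noisy
baseline measurement per replicate batch.

The default planted panel mirrors the screen's headline regulators — UAG
and AGG silencers, a UUU enhancer, a CG-core enhancer and the GCACC-type
silencer (planted flank-aware, so it covers ACC-at-position-1 pentamers) —
which exercises every classifier family downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .library import LibraryContext, MotifPattern, enumerate_library, match


def default_planted_effects() -> dict[MotifPattern, float]:
    return {
        MotifPattern("UAG"): -1.5,
        MotifPattern("AGG"): -1.2,
        MotifPattern("UUU"): +1.5,
        MotifPattern("CG"): +0.8,
        MotifPattern("GCACC", use_flanks=True): -2.5,
    }


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one simulated screen."""

    baseline_psi: float = 41.0
    planted_effects: dict = field(default_factory=default_planted_effects)
    noise_sd: float = 3.0
    n_replicates: int = 2
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.baseline_psi < 100:
            raise ValueError("baseline_psi must lie in (0, 100)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        for m in self.planted_effects:
            if not isinstance(m, MotifPattern):
                raise ValueError(f"planted effect key {m!r} is not a MotifPattern")


@dataclass(frozen=True)
class GroundTruth:
    """What was planted: per-pentamer true PSI and per-motif memberships."""

    true_psi: pd.Series
    planted_members: dict[str, tuple[str, ...]]
    planted_effects: dict[str, float]
    baseline_psi: float
    n_truncated: int

    def expected_sign(self, motif_key: str) -> int:
        return 1 if self.planted_effects[motif_key] > 0 else -1


def _pattern_key(m: MotifPattern) -> str:
    key = m.pattern
    if m.anchor != "anywhere":
        key += f"@{m.anchor}"
    if m.use_flanks:
        key += "+flanks"
    return key


def true_psi_of(pentamer: str, spec: SyntheticSpec,
                ctx: LibraryContext | None = None) -> float:
    """Closed-form true PSI of one pentamer under the planted model."""
    ctx = ctx or LibraryContext()
    eta = logit(spec.baseline_psi / 100.0)
    for motif, effect in spec.planted_effects.items():
        if match(pentamer, motif, ctx)[0]:
            eta += effect
    return float(100.0 * expit(eta))


def generate_psi_matrix(spec: SyntheticSpec,
                        ctx: LibraryContext | None = None
                        ) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate a (2·n_replicates) × 1024 PSI matrix plus its ground truth."""
    ctx = ctx or LibraryContext()
    library = enumerate_library(ctx)
    rng = np.random.default_rng(spec.seed)

    members = {
        _pattern_key(m): tuple(p for p in library if match(p, m, ctx)[0])
        for m in spec.planted_effects
    }
    effects = {_pattern_key(m): float(e) for m, e in spec.planted_effects.items()}
    true_psi = pd.Series([true_psi_of(p, spec, ctx) for p in library],
                         index=library, name="true_psi")

    rows = []
    index = []
    n_trunc = 0
    for r in range(1, spec.n_replicates + 1):
        mut_noise = rng.normal(0.0, spec.noise_sd, size=len(library))
        mut = true_psi.to_numpy() + mut_noise
        n_trunc += int(((mut < 0) | (mut > 100)).sum())
        mut = np.clip(mut, 0.0, 100.0)
        wt = spec.baseline_psi + rng.normal(0.0, spec.noise_sd)
        n_trunc += int(not 0 <= wt <= 100)
        wt = float(np.clip(wt, 0.0, 100.0))
        rows.append(mut)
        index.append(f"MUT_PSI_R{r}")
        rows.append(np.full(len(library), wt))
        index.append(f"WT_PSI_R{r}")

    matrix = pd.DataFrame(rows, index=index, columns=library)
    truth = GroundTruth(true_psi=true_psi, planted_members=members,
                        planted_effects=effects,
                        baseline_psi=spec.baseline_psi, n_truncated=n_trunc)
    return matrix, truth


def null_spec(seed: int = 0, noise_sd: float = 3.0,
              n_replicates: int = 2) -> SyntheticSpec:
    """A spec with no planted effects (pure noise around baseline)."""
    return SyntheticSpec(planted_effects={}, noise_sd=noise_sd,
                         n_replicates=n_replicates, seed=seed)


def evaluate_recovery(msea_results: pd.DataFrame, truth: GroundTruth,
                      sets) -> dict:
    """Did enrichment recover the planted motifs?

    For each planted motif the corresponding motif set is the scored set
    with the highest Jaccard overlap to the planted member list (ties
    broken by set_id).  A motif counts as recovered when that set is
    significant with the planted effect's sign.  The false-positive rate is
    the significant fraction among scored sets sharing no member with any
    planted motif.
    """
    by_id = sets.by_id()
    res = msea_results.set_index("set_id")
    planted_union: set[str] = set()
    per_motif = {}
    for key, members in truth.planted_members.items():
        mset = set(members)
        planted_union |= mset
        best_id, best_j = None, -1.0
        for sid in res.index:
            s = set(by_id[sid].members)
            j = len(s & mset) / len(s | mset)
            if j > best_j or (j == best_j and (best_id is None or sid < best_id)):
                best_id, best_j = sid, j
        row = res.loc[best_id]
        want = truth.expected_sign(key)
        got = 0 if row["nes"] == 0 or not np.isfinite(row["nes"]) else (
            1 if row["nes"] > 0 else -1)
        per_motif[key] = {
            "matched_set": best_id,
            "jaccard": best_j,
            "nes": float(row["nes"]),
            "fdr_q": float(row["fdr_q"]),
            "significant": bool(row["significant"]),
            "expected_sign": want,
            "observed_sign": got,
            "recovered": bool(row["significant"] and got == want),
        }

    unplanted = [sid for sid in res.index
                 if not (set(by_id[sid].members) & planted_union)]
    n_fp = int(res.loc[unplanted, "significant"].sum()) if unplanted else 0
    n_planted = len(per_motif)
    return {
        "per_motif": per_motif,
        "n_recovered": sum(m["recovered"] for m in per_motif.values()),
        "n_planted": n_planted,
        "power": (sum(m["recovered"] for m in per_motif.values()) / n_planted
                  if n_planted else float("nan")),
        "n_unplanted_scored": len(unplanted),
        "n_false_positive": n_fp,
        "false_positive_rate": n_fp / len(unplanted) if unplanted else 0.0,
    }
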