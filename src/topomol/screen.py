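"""Virtual-screening evaluation: AUC, enrichment factors, leave-one-target-out.

The AUC here is the rank-based form

    AUC = 1 - (1 / N_a) * sum_i  N_d^i / N_d,

where ``N_a`` and ``N_d`` count actives and decoys and ``N_d^i`` is the
number of decoys ranked above the i-th active (tied decoys count one
half, the Mann-Whitney convention). A random ranking has expectation 0.5
and a perfect ranking scores 1. The enrichment factor at x%

    EF_x% = (N_a^{x%} / N^{x%}) * (N / N_a)

compares the active fraction among the top x% ranked compounds (``N^{x%}``
= ceil(x N / 100)) with the overall active fraction; EF at 100% is 1 by
construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd


@dataclass
class ScreenEntry:
    compound_id: str
    target_id: str
    score: float
    label: str  # {"active", "decoy"}

    def __post_init__(self) -> None:
        if self.label not in ("active", "decoy"):
            raise ValueError(f"label must be 'active' or 'decoy', got {self.label!r}")


@dataclass
class ScreenResult:
    """Scored, labelled compounds; ranking is descending by score."""

    entries: list[ScreenEntry] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.entries)

    @classmethod
    def from_arrays(
        cls,
        scores: Sequence[float],
        labels: Sequence[str] | Sequence[int],
        target_id: str = "T",
        compound_ids: Sequence[str] | None = None,
    ) -> "ScreenResult":
        entries = []
        for k, (s, lab) in enumerate(zip(scores, labels)):
            if not isinstance(lab, str):
                lab = "active" if lab else "decoy"
            cid = compound_ids[k] if compound_ids is not None else f"c{k}"
            entries.append(ScreenEntry(cid, target_id, float(s), lab))
        return cls(entries)

    @property
    def n_actives(self) -> int:
        return sum(1 for e in self.entries if e.label == "active")

    @property
    def n_decoys(self) -> int:
        return sum(1 for e in self.entries if e.label == "decoy")

    def to_csv(self, path: str) -> None:
        pd.DataFrame(
            [(e.compound_id, e.target_id, e.score, e.label) for e in self.entries],
            columns=["compound_id", "target_id", "score", "label"],
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str) -> "ScreenResult":
        df = pd.read_csv(path)
        return cls(
            [
                ScreenEntry(str(r.compound_id), str(r.target_id), float(r.score), str(r.label))
                for r in df.itertuples()
            ]
        )


def auc(sr: ScreenResult) -> float:
    """Rank-based AUC; tied decoys contribute one half."""
    actives = np.array([e.score for e in sr.entries if e.label == "active"])
    decoys = np.array([e.score for e in sr.entries if e.label == "decoy"])
    if len(actives) == 0 or len(decoys) == 0:
        raise ValueError("AUC requires at least one active and one decoy")
    total = 0.0
    for a in actives:
        above = np.count_nonzero(decoys > a)
        ties = np.count_nonzero(decoys == a)
        total += above + 0.5 * ties
    return 1.0 - total / (len(actives) * len(decoys))


def enrichment_factor(sr: ScreenResult, x: float) -> float:
    """EF at the top x% of the descending-score ranking."""
    if not sr.entries:
        raise ValueError("empty ranking")
    if not (0 < x <= 100):
        raise ValueError("x must be in (0, 100]")
    n = len(sr.entries)
    n_a = sr.n_actives
    if n_a == 0:
        raise ValueError("no actives in ranking")
    top = math.ceil(x * n / 100.0)
    order = sorted(sr.entries, key=lambda e: -e.score)
    top_actives = sum(1 for e in order[:top] if e.label == "active")
    return (top_actives / top) * (n / n_a)


def leave_one_target_out(
    results_by_target: Mapping[str, ScreenResult],
    exclusions: Mapping[str, Sequence[str]] | None = None,
    ef_percents: Sequence[float] = (2.0, 20.0),
) -> pd.DataFrame:
    """Per-target AUC/EF table with an unweighted average row.

    ``results_by_target`` maps a target id to the scored test entries of
    that target's experiment. ``exclusions`` maps a target to the targets
    removed from its training set; it is bookkeeping recorded in the
    report (training happens upstream).
    """
    exclusions = exclusions or {}
    for t in exclusions:
        if t not in results_by_target:
            raise KeyError(f"exclusion refers to unknown target {t!r}")
    rows = []
    for target, sr in results_by_target.items():
        row = {"target": target, "AUC": auc(sr)}
        for x in ef_percents:
            row[f"EF{x:g}%"] = enrichment_factor(sr, x)
        row["excluded"] = ";".join(exclusions.get(target, ()))
        rows.append(row)
    df = pd.DataFrame(rows)
    avg = {"target": "average", "excluded": ""}
    for col in df.columns:
        if col not in ("target", "excluded"):
            avg[col] = df[col].mean()
    return pd.concat([df, pd.DataFrame([avg])], ignore_index=True)


def training_pool(
    all_targets: Sequence[str], test_target: str,
    exclusions: Mapping[str, Sequence[str]] | None = None,
) -> list[str]:
    """Targets available for training when testing on *test_target*."""
    excluded = set((exclusions or {}).get(test_target, ())) | {test_target}
    return [t for t in all_targets if t not in excluded]
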