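"""Pair and stimulus bookkeeping for the paired sentence design.

The experimental design consists of N sentence pairs (2N sentences). The
two members of a pair have distinct contexts but predict the same
sentence-final word (SFW); one member actually ends with that expected
word, the other with a plausible but unexpected one. Half of the predicted
SFWs are nouns, half verbs.

Two families of comparisons drive every similarity analysis:

* *within-pair* — the two members of the same pair (N comparisons),
* *between-pair* — every unordered cross-pair combination of sentences
  (2N(N-1) comparisons; for N = 120 that is 120*119*2 = 28560).

This module enumerates those sets, builds presentation orders under the
separation/run-length constraints of the design, and selects the control
subsets used to rule out confounds (matched between-pair subsample,
same-SFW-1 subset, expected-first vs unexpected-first split, and
within-syntactic-category comparisons).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PairDesign",
    "ComparisonSet",
    "random_design",
    "enumerate_within",
    "enumerate_between",
    "subsample_between",
    "enumerate_within_category",
    "split_by_order",
    "build_presentation_order",
    "select_same_sfw1_control",
    "compare_pair_properties",
    "OrderConstraintError",
]


class OrderConstraintError(RuntimeError):
    """Raised when no presentation order satisfying the constraints is found."""


@dataclass(frozen=True)
class ComparisonSet:
    """An unordered collection of sentence-id pairs under one condition label."""

    label: str
    comparisons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        for a, b in self.comparisons:
            if a == b:
                raise ValueError(f"sentence {a} compared with itself")

    def __len__(self) -> int:
        return len(self.comparisons)

    def __iter__(self):
        return iter(self.comparisons)

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        if not self.comparisons:
            return np.array([], dtype=int), np.array([], dtype=int)
        arr = np.asarray(self.comparisons, dtype=int)
        return arr[:, 0], arr[:, 1]


def _canon(a: int, b: int) -> tuple[int, int]:
    return (a, b) if a < b else (b, a)


@dataclass
class PairDesign:
    """Sentence/pair design table.

    ``table`` holds one row per sentence with columns: ``sentence_id``,
    ``pair_id``, ``member_index``, ``expectancy``, ``category``,
    ``sfw1_token`` and optionally ``presentation_position`` plus arbitrary
    per-sentence property columns.
    """

    table: pd.DataFrame
    properties: list[str] = field(default_factory=list)

    REQUIRED = ("sentence_id", "pair_id", "member_index", "expectancy", "category")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.table.columns:
                raise ValueError(f"design table missing column {col!r}")
        t = self.table
        if t["sentence_id"].duplicated().any():
            raise ValueError("duplicate sentence ids")
        for pid, grp in t.groupby("pair_id"):
            if len(grp) != 2:
                raise ValueError(f"pair {pid} has {len(grp)} members (expected 2)")
            if sorted(grp["member_index"]) != [1, 2]:
                raise ValueError(f"pair {pid} member indices must be {{1, 2}}")
            if set(grp["expectancy"]) != {"expected", "unexpected"}:
                raise ValueError(
                    f"pair {pid} must contain one expected and one unexpected member"
                )
        self.table = t.reset_index(drop=True)

    @property
    def n_pairs(self) -> int:
        return self.table["pair_id"].nunique()

    @property
    def n_sentences(self) -> int:
        return len(self.table)

    @property
    def pair_ids(self) -> list[int]:
        return sorted(self.table["pair_id"].unique())

    def sentences_of_pair(self, pair_id: int) -> tuple[int, int]:
        grp = self.table[self.table["pair_id"] == pair_id].sort_values("member_index")
        a, b = grp["sentence_id"].tolist()
        return int(a), int(b)

    def pair_of(self, sentence_id: int) -> int:
        row = self.table[self.table["sentence_id"] == sentence_id]
        if row.empty:
            raise KeyError(f"unknown sentence {sentence_id}")
        return int(row["pair_id"].iloc[0])

    def attribute(self, sentence_id: int, column: str):
        row = self.table[self.table["sentence_id"] == sentence_id]
        if row.empty:
            raise KeyError(f"unknown sentence {sentence_id}")
        return row[column].iloc[0]

    def pair_category(self, pair_id: int) -> str:
        grp = self.table[self.table["pair_id"] == pair_id]
        cats = set(grp["category"])
        if len(cats) != 1:
            raise ValueError(f"pair {pair_id} has mixed categories {cats}")
        return cats.pop()

    def with_presentation_order(self, order: np.ndarray) -> "PairDesign":
        """Attach per-sentence ordinal positions (``order[k]`` = sentence id
        presented at position k)."""
        pos = {int(sid): k for k, sid in enumerate(order)}
        t = self.table.copy()
        t["presentation_position"] = t["sentence_id"].map(pos)
        if t["presentation_position"].isna().any():
            raise ValueError("presentation order does not cover all sentences")
        return PairDesign(table=t, properties=list(self.properties))

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, properties: list[str] | None = None) -> "PairDesign":
        return cls(table=pd.read_csv(path), properties=properties or [])


def random_design(n_pairs: int, seed: int = 0, sfw1_shared_fraction: float = 0.0) -> PairDesign:
    """Build a design table with the canonical paired structure.

    Categories alternate noun/verb (a 50/50 split for even ``n_pairs``);
    which member is the expected-SFW one is randomized per pair.
    ``sfw1_shared_fraction`` makes that fraction of pairs reuse an SFW-1
    token drawn from a small shared pool (for the same-SFW-1 control);
    remaining sentences get unique tokens.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    shared_pool = [f"sfw1_shared_{k}" for k in range(max(1, n_pairs // 4))]
    for p in range(n_pairs):
        expected_member = int(rng.integers(1, 3))
        category = "noun" if p % 2 == 0 else "verb"
        for m in (1, 2):
            sid = 2 * p + m - 1
            if rng.random() < sfw1_shared_fraction:
                token = shared_pool[int(rng.integers(len(shared_pool)))]
            else:
                token = f"sfw1_{sid}"
            rows.append(
                dict(
                    sentence_id=sid,
                    pair_id=p,
                    member_index=m,
                    expectancy="expected" if m == expected_member else "unexpected",
                    category=category,
                    sfw1_token=token,
                )
            )
    return PairDesign(table=pd.DataFrame(rows))


def enumerate_within(design: PairDesign) -> ComparisonSet:
    """One comparison per pair: the two sentences predicting the same SFW."""
    comps = tuple(_canon(*design.sentences_of_pair(p)) for p in design.pair_ids)
    return ComparisonSet(label="within", comparisons=comps)


def enumerate_between(design: PairDesign) -> ComparisonSet:
    """All unordered sentence pairs whose members belong to different pairs.

    Count identity: 2N(N-1) for N pairs (C(2N, 2) minus the N within-pair
    comparisons).
    """
    t = design.table
    sids = t["sentence_id"].to_numpy()
    pids = t["pair_id"].to_numpy()
    comps = [
        _canon(int(sids[i]), int(sids[j]))
        for i, j in combinations(range(len(sids)), 2)
        if pids[i] != pids[j]
    ]
    return ComparisonSet(label="between", comparisons=tuple(sorted(comps)))


def subsample_between(cset: ComparisonSet, k: int, seed: int) -> ComparisonSet:
    """Uniform random subset of ``k`` comparisons (the matched-count control)."""
    if k > len(cset):
        raise ValueError(f"cannot subsample {k} from {len(cset)} comparisons")
    if k == len(cset):
        return ComparisonSet(label=cset.label, comparisons=cset.comparisons)
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(cset), size=k, replace=False)
    comps = tuple(cset.comparisons[i] for i in sorted(idx))
    return ComparisonSet(label=f"{cset.label}_subset", comparisons=comps)


def enumerate_within_category(
    design: PairDesign, include_within_pairs: bool = False
) -> ComparisonSet:
    """Cross-pair comparisons whose predicted SFWs share syntactic category.

    By default within-pair comparisons are excluded (they share the item
    itself, not only its category); set ``include_within_pairs`` for the
    inclusive variant.
    """
    t = design.table
    if t["category"].isna().any():
        raise ValueError("every sentence needs a category label")
    sids = t["sentence_id"].to_numpy()
    pids = t["pair_id"].to_numpy()
    cats = t["category"].to_numpy()
    comps = []
    for i, j in combinations(range(len(sids)), 2):
        if cats[i] != cats[j]:
            continue
        if pids[i] == pids[j] and not include_within_pairs:
            continue
        comps.append(_canon(int(sids[i]), int(sids[j])))
    return ComparisonSet(label="within_category", comparisons=tuple(sorted(comps)))


def split_by_order(design: PairDesign) -> dict[str, dict[str, ComparisonSet]]:
    """Partition pairs by whether the expected-SFW member was presented first.

    Returns ``{"expected_first": {"within": ..., "between": ...},
    "unexpected_first": {...}}`` where each between-set is restricted to
    sentences of pairs in that group.
    """
    t = design.table
    if "presentation_position" not in t.columns or t["presentation_position"].isna().any():
        raise ValueError("presentation_order not populated")
    groups: dict[str, list[int]] = {"expected_first": [], "unexpected_first": []}
    for pid in design.pair_ids:
        grp = t[t["pair_id"] == pid]
        pos = grp.set_index("expectancy")["presentation_position"]
        if pos["expected"] == pos["unexpected"]:
            raise ValueError(f"pair {pid}: tied presentation positions")
        key = "expected_first" if pos["expected"] < pos["unexpected"] else "unexpected_first"
        groups[key].append(pid)

    out: dict[str, dict[str, ComparisonSet]] = {}
    for key, pids in groups.items():
        sub = t[t["pair_id"].isin(pids)]
        if sub.empty:
            out[key] = {
                "within": ComparisonSet(label=f"within_{key}", comparisons=()),
                "between": ComparisonSet(label=f"between_{key}", comparisons=()),
            }
            continue
        subdesign = PairDesign(table=sub.reset_index(drop=True), properties=list(design.properties))
        w = enumerate_within(subdesign)
        b = enumerate_between(subdesign)
        out[key] = {
            "within": ComparisonSet(label=f"within_{key}", comparisons=w.comparisons),
            "between": ComparisonSet(label=f"between_{key}", comparisons=b.comparisons),
        }
    return out


def _order_violations(
    order: np.ndarray,
    pair_of: np.ndarray,
    expectancy_of: np.ndarray,
    min_separation: int,
    max_run: int,
) -> int:
    """Number of constraint violations of a candidate order (0 = valid)."""
    pos_of_pair: dict[int, list[int]] = {}
    for pos, sid in enumerate(order):
        pos_of_pair.setdefault(int(pair_of[sid]), []).append(pos)
    v = 0
    for positions in pos_of_pair.values():
        if len(positions) == 2:
            separation = abs(positions[1] - positions[0]) - 1  # sentences in between
            if separation < min_separation:
                v += 1
    run = 1
    for k in range(1, len(order)):
        if expectancy_of[order[k]] == expectancy_of[order[k - 1]]:
            run += 1
            if run > max_run:
                v += 1
        else:
            run = 1
    return v


def build_presentation_order(
    design: PairDesign,
    min_separation: int = 30,
    max_run: int = 3,
    seed: int = 0,
    max_attempts: int = 10_000,
) -> np.ndarray:
    """Presentation order with pair members >= ``min_separation`` sentences
    apart and at most ``max_run`` same-expectancy sentences in a row.

    Starts from a random shuffle and repairs violations by seeded random
    swaps that never increase the violation count (pure rejection sampling
    is hopeless at the design scale of 120 pairs / separation 30).
    Raises :class:`OrderConstraintError` after ``max_attempts`` swaps.
    """
    rng = np.random.default_rng(seed)
    t = design.table
    n = len(t)
    max_sid = int(t["sentence_id"].max())
    pair_of = np.full(max_sid + 1, -1, dtype=int)
    exp_of = np.zeros(max_sid + 1, dtype=int)
    for _, row in t.iterrows():
        pair_of[int(row["sentence_id"])] = int(row["pair_id"])
        exp_of[int(row["sentence_id"])] = 1 if row["expectancy"] == "expected" else 0

    order = t["sentence_id"].to_numpy().copy()
    rng.shuffle(order)
    v = _order_violations(order, pair_of, exp_of, min_separation, max_run)
    attempts = 0
    while v > 0:
        if attempts >= max_attempts:
            raise OrderConstraintError(
                f"no valid order after {max_attempts} swap attempts "
                f"({v} violations remain; min_separation={min_separation}, "
                f"max_run={max_run}, n_sentences={n})"
            )
        i, j = rng.integers(0, n, size=2)
        if i == j:
            attempts += 1
            continue
        order[i], order[j] = order[j], order[i]
        v_new = _order_violations(order, pair_of, exp_of, min_separation, max_run)
        if v_new <= v:
            v = v_new
        else:
            order[i], order[j] = order[j], order[i]
        attempts += 1
    return order


def select_same_sfw1_control(
    design: PairDesign,
) -> tuple[ComparisonSet, ComparisonSet]:
    """Control subsets based on a shared penultimate word (SFW-1).

    The between subset contains cross-pair sentence pairs whose SFW-1 token
    is identical although they predict different SFWs. The within subset
    contains the within-pair comparisons of the pairs represented in that
    between subset. Empty subsets are allowed.
    """
    t = design.table
    if "sfw1_token" not in t.columns:
        raise ValueError("design table has no sfw1_token column")
    sids = t["sentence_id"].to_numpy()
    pids = t["pair_id"].to_numpy()
    toks = t["sfw1_token"].to_numpy()
    between = []
    involved_pairs: set[int] = set()
    for i, j in combinations(range(len(sids)), 2):
        if pids[i] != pids[j] and toks[i] == toks[j]:
            between.append(_canon(int(sids[i]), int(sids[j])))
            involved_pairs.update((int(pids[i]), int(pids[j])))
    within = [
        _canon(*design.sentences_of_pair(p)) for p in sorted(involved_pairs)
    ]
    return (
        ComparisonSet(label="same_sfw_within", comparisons=tuple(sorted(within))),
        ComparisonSet(label="same_sfw1_between", comparisons=tuple(sorted(between))),
    )


def compare_pair_properties(
    design: PairDesign,
    property_columns: list[str] | None = None,
    categorical: set[str] | None = None,
) -> pd.DataFrame:
    """Independent two-sample t-tests on per-comparison difference codes.

    For each property, every comparison receives a code: 0/1 (members
    differ or not) for categorical properties, absolute difference for
    numeric ones. Within-pair codes (N values) are compared against
    between-pair codes (2N(N-1) values) with a pooled-variance t-test.
    Returns a DataFrame with columns property, t, df, p, degenerate.
    """
    props = property_columns if property_columns is not None else design.properties
    if not props:
        raise ValueError("no property columns given")
    categorical = categorical or set()
    within = enumerate_within(design)
    between = enumerate_between(design)
    t = design.table.set_index("sentence_id")
    rows = []
    for prop in props:
        if prop not in t.columns:
            raise ValueError(f"design table has no column {prop!r}")
        vals = t[prop]

        def codes(cset: ComparisonSet) -> np.ndarray:
            a, b = cset.as_arrays()
            va, vb = vals.loc[a].to_numpy(), vals.loc[b].to_numpy()
            if prop in categorical:
                return (va != vb).astype(float)
            return np.abs(va.astype(float) - vb.astype(float))

        cw, cb = codes(within), codes(between)
        if np.var(cw) == 0.0 and np.var(cb) == 0.0:
            tval = 0.0 if np.mean(cw) == np.mean(cb) else np.inf
            rows.append(dict(property=prop, t=tval, df=len(cw) + len(cb) - 2,
                             p=np.nan, degenerate=True))
            continue
        res = stats.ttest_ind(cw, cb, equal_var=True)
        rows.append(dict(property=prop, t=float(res.statistic),
                         df=len(cw) + len(cb) - 2, p=float(res.pvalue),
                         degenerate=False))
    return pd.DataFrame(rows)
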