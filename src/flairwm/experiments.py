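"""The four experimental split designs and the shuffle x run orchestration.

Family A splits each dataset 70/10/20 into train/val/test and then, for
indices above 0, downsizes train+val in ~10% steps while the test set stays
fixed; downsizing removes random scans but greedily preserves protocol
coverage. Family B draws identical per-protocol counts (default 5/1/1).
Family C holds entire protocols out for testing (strict 3D scans only).
Family D varies the number of protocols while keeping the train+val total
fixed. Class balance is enforced in every partition of every family.
"""

from __future__ import annotations

import dataclasses
import itertools
import warnings
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .evaluation import MetricsReport, compute_metrics
from .io import NEGATIVE, POSITIVE, ManifestEntry, ScanManifest, rng_from
from .preprocess import SLICES_2D_MAX, SLICES_3D_STRICT_MIN

TRAIN, VAL, TEST, UNUSED = "train", "val", "test", "unused"


@dataclasses.dataclass
class SplitAssignment:
    assignment: dict[str, str]           # scan_id -> train/val/test/unused
    shuffle_id: int = 0
    run_id: int = 0

    def ids(self, part: str) -> list[str]:
        return [s for s, p in self.assignment.items() if p == part]

    @property
    def train_ids(self):
        return self.ids(TRAIN)

    @property
    def val_ids(self):
        return self.ids(VAL)

    @property
    def test_ids(self):
        return self.ids(TEST)


@dataclasses.dataclass
class ExperimentSetting:
    family: str                          # "A" | "B" | "C" | "D"
    index: int = 0
    n_shuffles: int = 5
    n_runs: int = 2
    params: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in "ABCD" or len(self.family) != 1:
            raise ValueError("family must be one of A, B, C, D")


def _entry_map(manifest: ScanManifest) -> dict[str, ManifestEntry]:
    return {e.scan_id: e for e in manifest}


def _largest_remainder(n: int, fractions: Sequence[float],
                       priority: Sequence[int]) -> list[int]:
    """Integer apportionment of n by fractions; remainders go by fractional
    part, ties broken by the given priority order."""
    exact = [n * f for f in fractions]
    counts = [int(np.floor(e)) for e in exact]
    left = n - sum(counts)
    order = sorted(range(len(fractions)),
                   key=lambda i: (-(exact[i] - counts[i]), priority.index(i)))
    for i in range(left):
        counts[order[i % len(order)]] += 1
    return counts


def _split_by_class(entries: list[ManifestEntry], fractions: Sequence[float],
                    rng: np.random.Generator) -> dict[str, str]:
    """70/10/20-style split with class balance in every partition.

    Partition totals come from largest-remainder apportionment of the full
    pool (remainder priority: train, then test, validation last); classes
    are interleaved before slicing so any contiguous slice is balanced to
    within one scan.
    """
    pos = [e.scan_id for e in entries if e.label == POSITIVE]
    neg = [e.scan_id for e in entries if e.label == NEGATIVE]
    pos = [pos[i] for i in rng.permutation(len(pos))]
    neg = [neg[i] for i in rng.permutation(len(neg))]
    a, b = (pos, neg) if len(pos) >= len(neg) else (neg, pos)
    merged: list[str] = []
    ia = ib = 0
    for i in range(len(pos) + len(neg)):
        if (i % 2 == 0 and ia < len(a)) or ib >= len(b):
            merged.append(a[ia])
            ia += 1
        else:
            merged.append(b[ib])
            ib += 1
    counts = _largest_remainder(len(merged), fractions, priority=[0, 2, 1])
    out: dict[str, str] = {}
    start = 0
    for part, c in zip((TRAIN, VAL, TEST), counts):
        for s in merged[start:start + c]:
            out[s] = part
        start += c
    return out


def _downsize(pool_ids: list[str], entries: Mapping[str, ManifestEntry],
              assignment: Mapping[str, str], n_remove: int,
              rng: np.random.Generator) -> list[str]:
    """Remove n_remove scans from the train/val pool.

    Classes alternate and each removal comes from the partition whose picked
    class is most over-represented, so per-partition class balance stays
    within one; within that pool the scan is taken from the most-represented
    protocol, never a protocol's last scan while another still has two or
    more (protocol coverage is preserved as long as possible).
    """
    remaining = list(pool_ids)
    classes = itertools.cycle((POSITIVE, NEGATIVE))
    for _ in range(n_remove):
        cand: list[str] = []
        for _attempt in range(2):      # fall back to the other class if empty
            label = next(classes)
            cand = [s for s in remaining if entries[s].label == label]
            if cand:
                break
        if not cand:
            break
        # prefer the partition where this class currently outnumbers the other
        def surplus(part: str) -> tuple[int, int]:
            labs = [entries[s].label for s in remaining if assignment[s] == part]
            return (labs.count(label) - labs.count(
                NEGATIVE if label == POSITIVE else POSITIVE), len(labs))
        parts = sorted({assignment[s] for s in cand},
                       key=lambda p: surplus(p), reverse=True)
        cand = [s for s in cand if assignment[s] == parts[0]]
        proto_counts: dict[str, int] = {}
        for s in remaining:
            proto_counts[entries[s].protocol_id] = proto_counts.get(entries[s].protocol_id, 0) + 1
        cand.sort(key=lambda s: (-proto_counts[entries[s].protocol_id], s))
        # never take a protocol's last scan while another still has >= 2
        pick = cand[0]
        if proto_counts[entries[pick].protocol_id] == 1 and max(proto_counts.values()) >= 2:
            alt = [s for s in cand if proto_counts[entries[s].protocol_id] >= 2]
            if alt:
                pick = alt[0]
        remaining.remove(pick)
    return remaining


def make_setting_A(manifest: ScanManifest, index: int = 0, seed: int = 0,
                   fractions: tuple[float, float, float] = (0.7, 0.1, 0.2),
                   downsize_step: float = 0.1) -> SplitAssignment:
    """Per-dataset 70/10/20 split; for index > 0 the train+val pool is
    downsized by ~``downsize_step`` per index step while the test set keeps
    exactly the scans of index 0 (same seed)."""
    entries = _entry_map(manifest)
    assignment: dict[str, str] = {}
    for ds in manifest.datasets():
        ds_entries = [e for e in manifest if e.dataset_id == ds]
        n_classes = len({e.label for e in ds_entries})
        if len(ds_entries) < 3 or n_classes < 2:
            warnings.warn(f"dataset {ds} too small for a per-dataset split; "
                          "folding into the pooled split", stacklevel=2)
            continue
        assignment.update(_split_by_class(ds_entries, fractions,
                                          rng_from(seed, "A", ds)))
    pooled = [e for e in manifest if e.scan_id not in assignment]
    if pooled:
        assignment.update(_split_by_class(pooled, fractions,
                                          rng_from(seed, "A", "pooled")))
    if index > 0:
        pool = [s for s, p in assignment.items() if p in (TRAIN, VAL)]
        n_remove = min(int(round(index * downsize_step * len(pool))), len(pool) - 2)
        kept = set(_downsize(pool, entries, assignment, n_remove,
                             rng_from(seed, "A-down", index)))
        for s in pool:
            if s not in kept:
                assignment[s] = UNUSED
    return SplitAssignment(assignment)


def make_setting_B(manifest: ScanManifest,
                   per_protocol: tuple[int, int, int] = (5, 1, 1),
                   seed: int = 0) -> SplitAssignment:
    """Identical per-protocol counts in train/val/test; per-protocol class
    quotas alternate across protocols so each partition is balanced overall.
    Protocols that cannot fill their quotas are excluded with a warning."""
    assignment: dict[str, str] = {e.scan_id: UNUSED for e in manifest}
    usable = 0
    for i, proto in enumerate(manifest.protocols()):
        pe = [e for e in manifest if e.protocol_id == proto]
        rng = rng_from(seed, "B", proto)
        by_label = {lab: [e.scan_id for e in pe if e.label == lab] for lab in (POSITIVE, NEGATIVE)}
        for lab in by_label:
            by_label[lab] = [by_label[lab][j] for j in rng.permutation(len(by_label[lab]))]
        plan: list[tuple[str, str]] = []
        feasible = True
        for part, c, phase in zip((TRAIN, VAL, TEST), per_protocol, (0, 1, 0)):
            n_pos = (c + (i + phase) % 2) // 2
            n_neg = c - n_pos
            if len(by_label[POSITIVE]) < n_pos or len(by_label[NEGATIVE]) < n_neg:
                feasible = False
                break
            for _ in range(n_pos):
                plan.append((by_label[POSITIVE].pop(), part))
            for _ in range(n_neg):
                plan.append((by_label[NEGATIVE].pop(), part))
        if not feasible:
            warnings.warn(f"protocol {proto} cannot fill per-protocol quotas "
                          f"{per_protocol}; excluded", stacklevel=2)
            continue
        usable += 1
        for scan_id, part in plan:
            assignment[scan_id] = part
    if usable == 0:
        raise ValueError("no protocol can fill the per-protocol quotas")
    return SplitAssignment(assignment)


def make_setting_C(manifest: ScanManifest, case_id: int = 1, seed: int = 0,
                   n_train_protocols: int = 6, n_test_protocols: int = 2,
                   n_slices: Mapping[str, int] | None = None,
                   strict_min_slices: int = SLICES_3D_STRICT_MIN,
                   threshold_2d: int = SLICES_2D_MAX,
                   val_fraction: float = 0.15) -> SplitAssignment:
    """Held-out-protocol design: test protocols never appear in train/val.

    Only strict-3D scans (slice count >= ``strict_min_slices``) participate;
    2D scans (<= ``threshold_2d`` slices) and everything in between are
    marked unused. ``n_slices`` maps scan_id to slice count (omit to treat
    all scans as eligible, e.g. for phantoms generated at full grid).
    Enumerated cases rotate which protocol pair is held out.
    """
    assignment: dict[str, str] = {e.scan_id: UNUSED for e in manifest}

    def eligible(e: ManifestEntry) -> bool:
        if n_slices is None:
            return True
        return n_slices[e.scan_id] >= strict_min_slices

    elig = [e for e in manifest if eligible(e)]
    proto_sizes: dict[str, int] = {}
    for e in elig:
        proto_sizes[e.protocol_id] = proto_sizes.get(e.protocol_id, 0) + 1
    need = n_train_protocols + n_test_protocols
    if len(proto_sizes) < need:
        raise ValueError(f"need >= {need} eligible protocols, have {len(proto_sizes)}")
    chosen = sorted(sorted(proto_sizes), key=lambda p: -proto_sizes[p])[:need]
    combos = list(itertools.combinations(sorted(chosen), n_test_protocols))
    held_out = set(combos[(case_id - 1) % len(combos)])

    test_entries = [e for e in elig if e.protocol_id in held_out]
    trainval = [e for e in elig if e.protocol_id in set(chosen) - held_out]
    rng = rng_from(seed, "C", case_id)
    # balanced test: equal per-class counts
    n_per = min(sum(e.label == POSITIVE for e in test_entries),
                sum(e.label == NEGATIVE for e in test_entries))
    if n_per == 0:
        raise ValueError("held-out protocols lack one of the classes")
    for lab in (POSITIVE, NEGATIVE):
        ids = [e.scan_id for e in test_entries if e.label == lab]
        ids = [ids[i] for i in rng.permutation(len(ids))]
        for s in ids[:n_per]:
            assignment[s] = TEST
    assignment.update(_split_by_class(trainval, (1 - val_fraction, val_fraction, 0.0),
                                      rng_from(seed, "C-trainval", case_id)))
    # protocol isolation is structural; assert anyway
    train_protos = {e.protocol_id for e in manifest
                    if assignment[e.scan_id] in (TRAIN, VAL)}
    assert not train_protos & held_out, "protocol leakage between train and test"
    return SplitAssignment(assignment)


def make_setting_D(manifest: ScanManifest, n_protocols: int = 4,
                   total_train: int = 82, n_test: int = 20, seed: int = 0,
                   val_fraction: float = 0.125) -> SplitAssignment:
    """Fixed train+val total across varying protocol counts.

    The ``total_train`` scans (including validation) are drawn from the
    ``n_protocols`` most-populous protocols with per-protocol quotas that
    differ by at most 1; the test set is drawn from all selected protocols.
    """
    proto_sizes: dict[str, int] = {}
    for e in manifest:
        proto_sizes[e.protocol_id] = proto_sizes.get(e.protocol_id, 0) + 1
    if len(proto_sizes) < n_protocols:
        raise ValueError(f"manifest has {len(proto_sizes)} protocols, need {n_protocols}")
    chosen = sorted(sorted(proto_sizes), key=lambda p: -proto_sizes[p])[:n_protocols]
    assignment: dict[str, str] = {e.scan_id: UNUSED for e in manifest}

    base, extra = divmod(total_train, n_protocols)
    trainval_ids: list[str] = []
    test_pool: dict[str, list[str]] = {POSITIVE: [], NEGATIVE: []}
    for i, proto in enumerate(chosen):
        quota = base + (1 if i < extra else 0)
        pe = [e for e in manifest if e.protocol_id == proto]
        rng = rng_from(seed, "D", proto)
        by_label = {lab: [e.scan_id for e in pe if e.label == lab]
                    for lab in (POSITIVE, NEGATIVE)}
        for lab in by_label:
            by_label[lab] = [by_label[lab][j] for j in rng.permutation(len(by_label[lab]))]
        n_pos = (quota + i % 2) // 2
        n_neg = quota - n_pos
        if len(by_label[POSITIVE]) < n_pos or len(by_label[NEGATIVE]) < n_neg:
            raise ValueError(f"protocol {proto} cannot fill a quota of {quota} "
                             "class-balanced scans")
        trainval_ids += by_label[POSITIVE][:n_pos] + by_label[NEGATIVE][:n_neg]
        test_pool[POSITIVE] += by_label[POSITIVE][n_pos:]
        test_pool[NEGATIVE] += by_label[NEGATIVE][n_neg:]
    entries = _entry_map(manifest)
    assignment.update(_split_by_class([entries[s] for s in trainval_ids],
                                      (1 - val_fraction, val_fraction, 0.0),
                                      rng_from(seed, "D-split")))
    rng = rng_from(seed, "D-test")
    per_class = n_test // 2
    for lab in (POSITIVE, NEGATIVE):
        ids = test_pool[lab]
        if len(ids) < per_class:
            raise ValueError(f"not enough held-out {lab} scans for the test set")
        ids = [ids[i] for i in rng.permutation(len(ids))]
        for s in ids[:per_class]:
            assignment[s] = TEST
    return SplitAssignment(assignment)


_MAKERS: dict[str, Callable[..., SplitAssignment]] = {
    "A": make_setting_A, "B": make_setting_B,
    "C": make_setting_C, "D": make_setting_D,
}


def make_assignment(setting: ExperimentSetting, manifest: ScanManifest,
                    seed: int) -> SplitAssignment:
    kwargs = dict(setting.params)
    if setting.family == "A":
        kwargs.setdefault("index", setting.index)
    elif setting.family == "C":
        kwargs.setdefault("case_id", setting.index + 1)
    a = _MAKERS[setting.family](manifest, seed=seed, **kwargs)
    check_invariants(manifest, a, family=setting.family)
    return a


def check_invariants(manifest: ScanManifest, split: SplitAssignment,
                     family: str | None = None, balance_slack: int = 1) -> None:
    """Assert disjointness, per-partition class balance, and (family C)
    protocol isolation."""
    entries = _entry_map(manifest)
    parts: dict[str, list[str]] = {TRAIN: [], VAL: [], TEST: [], UNUSED: []}
    for s, p in split.assignment.items():
        parts[p].append(s)
    all_assigned = [s for p in (TRAIN, VAL, TEST) for s in parts[p]]
    assert len(all_assigned) == len(set(all_assigned)), "partitions overlap"
    for p in (TRAIN, VAL, TEST):
        labs = [entries[s].label for s in parts[p]]
        n_pos = labs.count(POSITIVE)
        assert abs(2 * n_pos - len(labs)) <= balance_slack, \
            f"{p} partition unbalanced: {n_pos}/{len(labs) - n_pos}"
    if family == "C":
        train_protos = {entries[s].protocol_id for p in (TRAIN, VAL) for s in parts[p]}
        test_protos = {entries[s].protocol_id for s in parts[TEST]}
        assert not train_protos & test_protos, "family C protocol leakage"


def run_experiment(setting: ExperimentSetting, manifest: ScanManifest,
                   data: Mapping[str, np.ndarray], pipeline_factory: Callable,
                   seed: int = 0) -> tuple[pd.DataFrame, dict[str, tuple[float, float]]]:
    """Run the shuffle x run grid for one setting.

    ``data`` maps scan_id to the prepared classifier input volume. Returns a
    tidy results table (one row per shuffle x run with all metrics) and the
    mean +- sd aggregate per metric. Fully reproducible from ``seed``.
    """
    entries = _entry_map(manifest)
    rows = []
    for s in range(setting.n_shuffles):
        split = make_assignment(setting, manifest, seed=rng_from(seed, "shuffle", s).integers(2**31))
        xtr, ytr = _collect(split.train_ids, data, entries)
        xva, yva = _collect(split.val_ids, data, entries)
        xte, yte = _collect(split.test_ids, data, entries)
        for r in range(setting.n_runs):
            pipe = pipeline_factory(rng_from(seed, "model", s, r).integers(2**31))
            pipe.fit(xtr, ytr, xva, yva)
            probs = pipe.predict_proba(xte)
            report = compute_metrics(yte, (probs >= 0.5).astype(int), probs)
            row = {"shuffle": s, "run": r}
            row.update({k: getattr(report, k) for k in
                        ("accuracy", "sensitivity", "specificity", "precision",
                         "f1", "auroc", "mlcps_percent")})
            rows.append(row)
    table = pd.DataFrame(rows)
    metrics = [c for c in table.columns if c not in ("shuffle", "run")]
    aggregate = {m: (float(table[m].mean()), float(table[m].std(ddof=1)))
                 for m in metrics}
    return table, aggregate


def _collect(ids: list[str], data: Mapping[str, np.ndarray],
             entries: Mapping[str, ManifestEntry]) -> tuple[np.ndarray, np.ndarray]:
    ids = sorted(ids)
    x = np.stack([data[s] for s in ids])
    y = np.array([1 if entries[s].label == POSITIVE else 0 for s in ids])
    return x, y
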