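"""Candidate-site enumeration, negative balancing, identity-aware splitting
and Monte Carlo resampling."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .alphabet import (
    AlphabetError,
    EncodedWindow,
    LabelChannel,
    ModAlphabet,
    apply_labels,
    extract_window,
)

logger = logging.getLogger(__name__)


class DatasetError(ValueError):
    pass


@dataclass(frozen=True)
class SiteRecord:
    """One candidate site with its encoded window."""

    protein_id: str
    position: int  # 1-based
    residue: str
    label: int  # 1 = modified
    window: EncodedWindow

    @property
    def key(self) -> tuple[str, int]:
        return (self.protein_id, self.position)


@dataclass
class DatasetSplit:
    """Disjoint train/validation/test partitions of site records."""

    train: list[SiteRecord]
    validation: list[SiteRecord]
    test: list[SiteRecord]
    seed: int
    ratios: tuple[float, float, float] = (0.8, 0.1, 0.1)
    n_test_removed_identity: int = 0

    @property
    def n_total(self) -> int:
        return len(self.train) + len(self.validation) + len(self.test)

    def partitions(self) -> dict[str, list[SiteRecord]]:
        return {"train": self.train, "validation": self.validation, "test": self.test}


def enumerate_candidates(
    proteins: dict[str, str],
    residue_targets: set[str],
    positives: set[tuple[str, int]],
    channels: list[LabelChannel],
    k: int,
    alphabet: ModAlphabet,
) -> list[SiteRecord]:
    """One record per occurrence of a target residue in ``proteins``.

    Windows are cut from the *labeled* sequence (known sites replaced by mod
    tokens) with the center masked back to its plain residue.  ``positives``
    are (protein_id, 1-based position) pairs and must sit on target residues.
    """
    targets = set(residue_targets)
    for pid, pos in positives:
        seq = proteins.get(pid)
        if seq is None:
            raise DatasetError(f"positive site on unknown protein {pid!r}")
        if not 1 <= pos <= len(seq) or seq[pos - 1] not in targets:
            res = seq[pos - 1] if 1 <= pos <= len(seq) else "<out of range>"
            raise DatasetError(
                f"positive site {pid}:{pos} is {res!r}, not a target residue "
                f"{sorted(targets)}"
            )

    records: list[SiteRecord] = []
    for pid in proteins:
        seq = proteins[pid]
        labeled = apply_labels(seq, channels, alphabet, protein_id=pid)
        for i, res in enumerate(seq):
            if res not in targets:
                continue
            pos = i + 1
            win = extract_window(
                labeled, pos, k, alphabet, center_residue=res, protein_id=pid
            )
            records.append(
                SiteRecord(
                    protein_id=pid,
                    position=pos,
                    residue=res,
                    label=int((pid, pos) in positives),
                    window=win,
                )
            )
    return records


def balance_negatives(
    records: list[SiteRecord], seed: int, *, skip: bool = False
) -> list[SiteRecord]:
    """Keep all positives plus an equally sized random negative subsample.

    ``skip=True`` keeps every negative (for datasets that are already close
    to balanced).  If there are fewer negatives than positives, all negatives
    are kept with a warning.
    """
    pos = [r for r in records if r.label == 1]
    neg = [r for r in records if r.label == 0]
    if not pos:
        raise DatasetError("no positive sites: nothing to train on")
    if skip:
        return list(records)
    if len(neg) < len(pos):
        logger.warning(
            "only %d negatives for %d positives; keeping all negatives",
            len(neg), len(pos),
        )
        chosen = neg
    else:
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(neg), size=len(pos), replace=False)
        chosen = [neg[i] for i in sorted(idx)]
    return pos + chosen


def split_dataset(
    records: list[SiteRecord],
    ratios: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> DatasetSplit:
    """Random 80/10/10 split; test windows identical to a train/validation
    window are always dropped (exact-identity guarantee)."""
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise DatasetError(f"ratios {ratios} do not sum to 1")
    n = len(records)
    if n < 10:
        raise DatasetError(f"need at least 10 records to split, got {n}")
    n_val = round(ratios[1] * n)
    n_test = round(ratios[2] * n)

    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    test = [records[i] for i in order[:n_test]]
    validation = [records[i] for i in order[n_test : n_test + n_val]]
    train = [records[i] for i in order[n_test + n_val :]]

    split = DatasetSplit(train=train, validation=validation, test=test, seed=seed,
                         ratios=ratios)
    return identity_filter(split, 1.0)


def _identity_matrix(test_codes: np.ndarray, ref_codes: np.ndarray) -> np.ndarray:
    """Fraction of identical positions for every test x reference pair."""
    # (T, 1, k) == (1, R, k) -> (T, R); chunk the test axis to bound memory
    k = test_codes.shape[1]
    out = np.empty((test_codes.shape[0], ref_codes.shape[0]), dtype=np.float64)
    step = max(1, 2_000_000 // max(1, ref_codes.shape[0] * k))
    for i in range(0, test_codes.shape[0], step):
        chunk = test_codes[i : i + step]
        out[i : i + step] = (
            chunk[:, None, :] == ref_codes[None, :, :]
        ).sum(axis=2) / k
    return out


def identity_filter(split: DatasetSplit, cutoff: float) -> DatasetSplit:
    """Drop test records whose window is too similar to any train/validation
    window.

    Identity is ungapped position-wise: matching positions divided by k, mod
    tokens matching only themselves.  ``cutoff=1.0`` removes exact duplicates
    only; ``cutoff<1.0`` removes every test window with identity >= cutoff.
    """
    if not 0.0 < cutoff <= 1.0:
        raise DatasetError(f"identity cutoff must be in (0, 1], got {cutoff}")
    if not split.test:
        return split
    ref = split.train + split.validation
    if not ref:
        return split

    if cutoff == 1.0:
        ref_tokens = {r.window.tokens for r in ref}
        kept = [r for r in split.test if r.window.tokens not in ref_tokens]
    else:
        test_codes = np.stack([r.window.codes for r in split.test])
        ref_codes = np.stack([r.window.codes for r in ref])
        if test_codes.shape[1] != ref_codes.shape[1]:
            raise DatasetError("window lengths differ between partitions")
        ident = _identity_matrix(test_codes, ref_codes)
        keep_mask = (ident < cutoff).all(axis=1)
        kept = [r for r, keep in zip(split.test, keep_mask) if keep]

    removed = len(split.test) - len(kept)
    if removed:
        logger.info("identity_filter(cutoff=%.2f): removed %d test records",
                    cutoff, removed)
    return replace(
        split,
        test=kept,
        n_test_removed_identity=split.n_test_removed_identity + removed,
    )


def monte_carlo_resample(
    records: list[SiteRecord],
    n_folds: int = 10,
    seeds: list[int] | None = None,
    *,
    ratios: tuple[float, float, float] = (0.8, 0.1, 0.1),
    balance: bool = True,
) -> list[DatasetSplit]:
    """Repeated random resplitting with a fresh negative subsample per fold.

    ``records`` is the full (unbalanced) candidate pool; every fold draws its
    own negatives, then its own random split.
    """
    if seeds is None:
        seeds = list(range(n_folds))
    if len(seeds) != n_folds:
        raise DatasetError(f"{n_folds} folds require {n_folds} seeds, got {len(seeds)}")
    if len(records) < n_folds:
        raise DatasetError(
            f"{len(records)} records cannot support {n_folds} folds"
        )
    folds = []
    for seed in seeds:
        pool = balance_negatives(records, seed) if balance else list(records)
        folds.append(split_dataset(pool, ratios=ratios, seed=seed))
    return folds


def split_manifest_rows(folds: list[DatasetSplit]) -> list[dict]:
    """Flatten folds to manifest rows (fold, partition, protein, position, label)."""
    rows = []
    for fold_i, split in enumerate(folds):
        for part, recs in split.partitions().items():
            for r in recs:
                rows.append(
                    {
                        "fold": fold_i,
                        "partition": part,
                        "protein_id": r.protein_id,
                        "position": r.position,
                        "label": r.label,
                        "seed": split.seed,
                    }
                )
    return rows
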