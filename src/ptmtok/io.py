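"""Readers and writers for the package's plain-text formats.

Formats: FASTA (optionally with inline ``@``/``&`` tokens marking known
modified residues), site-annotation TSV (``protein_id\tposition\tmod_type``,
1-based positions), split-manifest TSV, and prediction CSV.
"""

from __future__ import annotations

import csv
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alphabet import (
    MOD_TOKENS,
    AlphabetError,
    LabelChannel,
    ModAlphabet,
    normalize_sequence,
)


def read_fasta(path, *, strict: bool = False) -> dict[str, str]:
    """Plain FASTA to ``{id: normalized sequence}`` (order preserved)."""
    proteins: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        proteins[rec.id] = normalize_sequence(str(rec.seq), strict=strict)
    return proteins


def write_fasta(proteins: dict[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=pid, description="") for pid, seq in proteins.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta_with_tokens(
    path, alphabet: ModAlphabet, *, strict: bool = False
) -> tuple[dict[str, str], list[LabelChannel]]:
    """FASTA whose sequences may carry inline mod tokens.

    Tokens are stripped to their plain residues (recovered through the
    alphabet's mod map) and returned as label channels, so downstream code
    sees a single convention: plain sequences plus explicit site lists.
    """
    proteins: dict[str, str] = {}
    sites: dict[str, dict[str, set[int]]] = {}  # mod_type -> pid -> positions
    residues_of: dict[str, set[str]] = {}

    for rec in SeqIO.parse(str(path), "fasta"):
        raw = str(rec.seq).upper()
        chars = []
        for i, c in enumerate(raw):
            if c in MOD_TOKENS and c not in alphabet.mod_tokens:
                raise AlphabetError(
                    f"{rec.id} position {i + 1}: token {c!r} has no meaning "
                    "under the selected model's alphabet"
                )
            if c in alphabet.mod_tokens:
                try:
                    mod_type, residue = alphabet.residue_for_token(c)
                except AlphabetError as exc:
                    raise AlphabetError(
                        f"{rec.id} position {i + 1}: {exc}"
                    ) from None
                sites.setdefault(mod_type, {}).setdefault(rec.id, set()).add(i + 1)
                residues_of.setdefault(mod_type, set()).add(residue)
                chars.append(residue)
            else:
                chars.append(c)
        proteins[rec.id] = normalize_sequence("".join(chars), strict=strict)

    channels = [
        LabelChannel(
            modification_type=mt,
            residue_targets=frozenset(residues_of[mt]),
            sites={pid: frozenset(ps) for pid, ps in by_pid.items()},
        )
        for mt, by_pid in sites.items()
    ]
    return proteins, channels


def write_labeled_fasta(
    proteins: dict[str, str],
    channels: list[LabelChannel],
    alphabet: ModAlphabet,
    path,
) -> None:
    """Emit FASTA with known sites replaced by their inline mod tokens."""
    from .alphabet import apply_labels

    labeled = {
        pid: apply_labels(seq, channels, alphabet, protein_id=pid)
        for pid, seq in proteins.items()
    }
    write_fasta(labeled, path)


# ---- site TSV -------------------------------------------------------------

SITE_COLUMNS = ("protein_id", "position", "mod_type")


def read_sites_tsv(path) -> list[tuple[str, int, str]]:
    """Rows of (protein_id, 1-based position, mod_type); header optional."""
    rows: list[tuple[str, int, str]] = []
    with open(path, newline="") as fh:
        for ln, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or row[0].startswith("#"):
                continue
            if ln == 1 and row[0] == "protein_id":
                continue
            if len(row) < 3:
                raise ValueError(f"{path}:{ln}: expected 3 columns, got {len(row)}")
            try:
                pos = int(row[1])
            except ValueError:
                raise ValueError(f"{path}:{ln}: position {row[1]!r} is not an integer")
            if pos < 1:
                raise ValueError(f"{path}:{ln}: position must be 1-based (>= 1)")
            rows.append((row[0], pos, row[2]))
    return rows


def write_sites_tsv(sites, mod_type: str, path) -> None:
    """``sites`` is an iterable of (protein_id, position)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(SITE_COLUMNS)
        for pid, pos in sorted(sites):
            w.writerow([pid, pos, mod_type])


def sites_to_channel(
    rows: list[tuple[str, int, str]],
    mod_type: str,
    residue_targets: set[str],
) -> LabelChannel:
    sites: dict[str, set[int]] = {}
    for pid, pos, mt in rows:
        if mt == mod_type:
            sites.setdefault(pid, set()).add(pos)
    return LabelChannel(
        modification_type=mod_type,
        residue_targets=frozenset(residue_targets),
        sites={pid: frozenset(ps) for pid, ps in sites.items()},
    )


# ---- split manifest -------------------------------------------------------

MANIFEST_COLUMNS = ("fold", "partition", "protein_id", "position", "label", "seed")


def write_split_manifest(rows: list[dict], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=MANIFEST_COLUMNS, delimiter="\t",
                           lineterminator="\n")
        w.writeheader()
        w.writerows(rows)


def read_split_manifest(path) -> list[dict]:
    with open(path, newline="") as fh:
        rows = []
        for row in csv.DictReader(fh, delimiter="\t"):
            row["fold"] = int(row["fold"])
            row["position"] = int(row["position"])
            row["label"] = int(row["label"])
            row["seed"] = int(row["seed"])
            rows.append(row)
        return rows


# ---- prediction CSV -------------------------------------------------------

PREDICTION_COLUMNS = (
    "protein_id", "position", "residue", "probability", "model_id", "call"
)


def write_predictions_csv(rows: list[dict], path) -> None:
    """Rows sorted by protein then position; probabilities to 6 decimals."""
    with open(path, "w", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=PREDICTION_COLUMNS, lineterminator="\n")
        w.writeheader()
        for row in sorted(rows, key=lambda r: (r["protein_id"], r["position"])):
            out = dict(row)
            out["probability"] = f"{row['probability']:.6f}"
            w.writerow(out)


def read_predictions_csv(path) -> list[dict]:
    with open(path, newline="") as fh:
        rows = []
        for row in csv.DictReader(fh):
            row["position"] = int(row["position"])
            row["probability"] = float(row["probability"])
            row["call"] = int(row["call"])
            rows.append(row)
        return rows


def write_proximity_tsv(hist, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["offset", "count", "normalized", "stratum"])
        for off, cnt, norm in zip(
            hist.offsets.tolist(), hist.counts.tolist(), hist.normalized.tolist()
        ):
            w.writerow([off, cnt, f"{norm:.6f}", hist.stratum])


def write_frequency_matrix(mat, offsets, tokens, path) -> None:
    """Position-frequency matrix: rows = tokens, columns = offsets."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["token"] + [str(o) for o in offsets])
        for tok, row in zip(tokens, mat.tolist()):
            w.writerow([tok] + row)
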