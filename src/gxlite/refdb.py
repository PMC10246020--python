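"""Reference database: packed subject sequences + h-mer index + taxonomy.

The index maps each canonical 38-bit h-mer key to its postings: strand-
signed positions of the windows that produced the key. H-mers are
collected with a 10 bp stride for prokaryote-like subjects and a 20 bp
stride for eukaryotes, anchored at subject position 0. Windows
containing ambiguity codes are skipped. An exclusion list removes
postings from flagged ranges without rebuilding the database.

A posting is packed into an int64 as ``subject_idx << 33 | pos << 1 |
canon_fwd`` where pos is the 0-based window start on the forward strand
and canon_fwd records whether the canonical (minword) orientation of
that window equals forward — the strand sign of the posting.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

from . import _seq
from .hmer import PRIMARY_WINDOW, window_keys
from .taxonomy import PROKARYOTE_LIKE, Taxonomy, read_seq_tax_map, write_seq_tax_map

logger = logging.getLogger(__name__)

FORMAT_VERSION = 1

STRIDE_PROK = 10
STRIDE_EUK = 20

_POS_SHIFT = 1
_SUBJ_SHIFT = 33


def pack_posting(subject_idx: int, pos: int, canon_fwd: bool) -> int:
    return (subject_idx << _SUBJ_SHIFT) | (pos << _POS_SHIFT) | int(canon_fwd)


def unpack_posting(p: int) -> tuple[int, int, bool]:
    return p >> _SUBJ_SHIFT, (p >> _POS_SHIFT) & ((1 << 32) - 1), bool(p & 1)


@dataclass
class SubjectRecord:
    """One reference sequence with its 2-bit-packable code array."""

    subject_id: str
    tax_id: int
    length: int
    codes: np.ndarray  # uint8 base codes, INVALID allowed (excluded from packing)


@dataclass
class ReferenceDB:
    subjects: list[SubjectRecord]
    index: dict[int, np.ndarray]  # key -> int64 posting array
    taxonomy: Taxonomy
    window_len: int = PRIMARY_WINDOW
    stride_prok: int = STRIDE_PROK
    stride_euk: int = STRIDE_EUK
    exclusion_list: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self):
        self._subject_idx = {s.subject_id: i for i, s in enumerate(self.subjects)}

    def subject_index(self, subject_id: str) -> int:
        return self._subject_idx[subject_id]

    def subject(self, subject_id: str) -> SubjectRecord:
        return self.subjects[self._subject_idx[subject_id]]

    def lookup(self, key: int) -> np.ndarray:
        """Postings for a canonical key (empty array if absent)."""
        return self.index.get(key, _EMPTY_POSTINGS)

    def n_postings(self, subject_id: str | None = None) -> int:
        if subject_id is None:
            return sum(len(v) for v in self.index.values())
        si = self._subject_idx[subject_id]
        return sum(
            int(np.count_nonzero((v >> _SUBJ_SHIFT) == si)) for v in self.index.values()
        )

    # ----- persistence ----------------------------------------------

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        manifest = {
            "format_version": FORMAT_VERSION,
            "window_len": self.window_len,
            "stride_prok": self.stride_prok,
            "stride_euk": self.stride_euk,
            "n_subjects": len(self.subjects),
            "n_keys": len(self.index),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
        self.taxonomy.to_tsv(out / "taxonomy.tsv")
        write_seq_tax_map(
            {s.subject_id: s.tax_id for s in self.subjects}, out / "seq_tax.tsv"
        )
        with open(out / "subjects.tsv", "w") as fh:
            fh.write("subject_id\tlength\n")
            for s in self.subjects:
                fh.write(f"{s.subject_id}\t{s.length}\n")
        packed = {}
        for i, s in enumerate(self.subjects):
            codes = s.codes.copy()
            codes[codes >= 4] = 0  # ambiguity positions are not indexed anyway
            packed[f"seq{i}"] = _seq.pack_2bit(codes)
            packed[f"amb{i}"] = np.flatnonzero(s.codes >= 4).astype(np.int64)
        np.savez_compressed(out / "sequences.npz", **packed)
        keys = np.fromiter(self.index.keys(), dtype=np.uint64, count=len(self.index))
        order = np.argsort(keys, kind="stable")
        keys = keys[order]
        vals = [self.index[int(k)] for k in keys]
        counts = np.array([len(v) for v in vals], dtype=np.int64)
        postings = np.concatenate(vals) if vals else np.zeros(0, dtype=np.int64)
        np.savez_compressed(
            out / "index.npz", keys=keys, counts=counts, postings=postings
        )
        with open(out / "exclusion.tsv", "w") as fh:
            fh.write("subject_id\tstart\tend\n")
            for sid, a, b in self.exclusion_list:
                fh.write(f"{sid}\t{a}\t{b}\n")

    @classmethod
    def load(cls, db_dir: str | Path) -> "ReferenceDB":
        db = Path(db_dir)
        manifest = json.loads((db / "manifest.json").read_text())
        if manifest["format_version"] != FORMAT_VERSION:
            raise ValueError(f"unsupported database format: {manifest}")
        taxonomy = Taxonomy.from_tsv(db / "taxonomy.tsv")
        tax_map = read_seq_tax_map(db / "seq_tax.tsv")
        subjects = []
        seqs = np.load(db / "sequences.npz")
        with open(db / "subjects.tsv") as fh:
            next(fh)
            for i, line in enumerate(fh):
                sid, length = line.rstrip("\n").split("\t")
                length = int(length)
                codes = _seq.unpack_2bit(seqs[f"seq{i}"], length)
                amb = seqs[f"amb{i}"]
                if len(amb):
                    codes[amb] = _seq.INVALID
                subjects.append(SubjectRecord(sid, tax_map[sid], length, codes))
        idx_file = np.load(db / "index.npz")
        keys, counts, postings = (
            idx_file["keys"],
            idx_file["counts"],
            idx_file["postings"],
        )
        bounds = np.concatenate([[0], np.cumsum(counts)])
        index = {
            int(k): postings[bounds[i] : bounds[i + 1]]
            for i, k in enumerate(keys)
        }
        exclusions = []
        with open(db / "exclusion.tsv") as fh:
            next(fh)
            for line in fh:
                sid, a, b = line.rstrip("\n").split("\t")
                exclusions.append((sid, int(a), int(b)))
        return cls(
            subjects,
            index,
            taxonomy,
            window_len=manifest["window_len"],
            stride_prok=manifest["stride_prok"],
            stride_euk=manifest["stride_euk"],
            exclusion_list=exclusions,
        )


_EMPTY_POSTINGS = np.zeros(0, dtype=np.int64)


def _read_fasta(paths: Iterable[str | Path]):
    seen = False
    for path in paths:
        for rec in SeqIO.parse(str(path), "fasta"):
            seen = True
            yield rec.id, str(rec.seq)
    if not seen:
        raise ValueError("no FASTA records found in input")


def build_index(
    fasta_paths: Sequence[str | Path],
    tax_map: dict[str, int],
    taxonomy: Taxonomy,
    window_len: int = PRIMARY_WINDOW,
    stride_prok: int = STRIDE_PROK,
    stride_euk: int = STRIDE_EUK,
) -> ReferenceDB:
    """Build a reference database from FASTA files and a taxonomy.

    Every record id must be present in ``tax_map`` and its tax-id in
    ``taxonomy`` (hard error otherwise). Stride is chosen per subject
    from the kingdom of its tax-id.
    """
    subjects: list[SubjectRecord] = []
    all_keys: list[np.ndarray] = []
    all_postings: list[np.ndarray] = []
    for sid, seq in _read_fasta(fasta_paths):
        if sid not in tax_map:
            raise ValueError(f"sequence {sid!r} has no tax-id mapping")
        tax_id = tax_map[sid]
        if tax_id not in taxonomy:
            raise ValueError(f"tax-id {tax_id} (sequence {sid!r}) not in taxonomy")
        codes = _seq.encode(seq)
        idx = len(subjects)
        subjects.append(SubjectRecord(sid, tax_id, len(codes), codes))
        stride = (
            stride_prok
            if taxonomy.kingdom(tax_id) in PROKARYOTE_LIKE
            else stride_euk
        )
        keys, canon, valid = window_keys(codes, window_len)
        starts = np.arange(0, len(keys), stride)
        ok = starts[valid[starts]]
        if len(ok) == 0:
            continue
        all_keys.append(keys[ok])
        all_postings.append(
            (np.int64(idx) << _SUBJ_SHIFT)
            | (ok.astype(np.int64) << _POS_SHIFT)
            | canon[ok].astype(np.int64)
        )
    index = _group_postings(all_keys, all_postings)
    return ReferenceDB(
        subjects,
        index,
        taxonomy,
        window_len=window_len,
        stride_prok=stride_prok,
        stride_euk=stride_euk,
    )


def _group_postings(
    key_arrays: list[np.ndarray], posting_arrays: list[np.ndarray]
) -> dict[int, np.ndarray]:
    if not key_arrays:
        return {}
    keys = np.concatenate(key_arrays)
    postings = np.concatenate(posting_arrays)
    order = np.argsort(keys, kind="stable")
    keys, postings = keys[order], postings[order]
    uniq, starts = np.unique(keys, return_index=True)
    bounds = np.append(starts, len(keys))
    return {
        int(k): postings[bounds[i] : bounds[i + 1]].copy()
        for i, k in enumerate(uniq)
    }


def apply_exclusion_list(
    db: ReferenceDB, entries: Iterable[tuple[str, int, int]]
) -> ReferenceDB:
    """Drop postings whose windows intersect excluded (subject, start,
    end) ranges; unknown subject ids are skipped with a warning.

    Ranges are 0-based half-open on the subject. Returns the same
    database object, modified in place.
    """
    by_subject: dict[int, list[tuple[int, int]]] = {}
    for sid, start, end in entries:
        if sid not in db._subject_idx:
            logger.warning("exclusion entry for unknown subject %r skipped", sid)
            continue
        by_subject.setdefault(db.subject_index(sid), []).append((start, end))
        db.exclusion_list.append((sid, start, end))
    if not by_subject:
        return db
    w = db.window_len
    dead_keys = []
    for key, postings in db.index.items():
        si = postings >> _SUBJ_SHIFT
        pos = (postings >> _POS_SHIFT) & ((1 << 32) - 1)
        keep = np.ones(len(postings), dtype=bool)
        for idx, ranges in by_subject.items():
            mine = si == idx
            if not mine.any():
                continue
            for start, end in ranges:
                # window [pos, pos+w) intersects [start, end)
                hit = mine & (pos < end) & (pos + w > start)
                keep &= ~hit
        if not keep.all():
            if keep.any():
                db.index[key] = postings[keep]
            else:
                dead_keys.append(key)
    for key in dead_keys:
        del db.index[key]
    return db
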