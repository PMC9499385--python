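"""Small-RNA read cleaning for randomized-adapter (4N) libraries.

Stage order per read: (1) trim at the leftmost 3' adapter occurrence,
allowing partial terminal matches of >= 6 bases at a 10% mismatch rate;
(2) strip the 4 randomized bases from each end of the insert; (3) keep
inserts of 16-28 nt inclusive. Reads without adapter evidence are
discarded — an untrimmed read still carries its 3' randomized bases at an
unknown position and cannot be classified downstream. Quality strings are
passed through untouched.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path

from .errors import ParseError

DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"


@dataclass
class PreprocessStats:
    """Read-accounting for one FASTQ; categories partition the input."""

    input_reads: int = 0
    adapter_found: int = 0
    passed_length: int = 0
    discarded_no_adapter: int = 0
    discarded_length: int = 0

    def check(self) -> None:
        assert self.input_reads == self.passed_length + self.discarded_no_adapter + self.discarded_length

    def as_dict(self) -> dict[str, int]:
        return {
            "input_reads": self.input_reads,
            "adapter_found": self.adapter_found,
            "passed_length": self.passed_length,
            "discarded_no_adapter": self.discarded_no_adapter,
            "discarded_length": self.discarded_length,
        }


def trim_adapter(
    sequence: str,
    adapter: str = DEFAULT_ADAPTER,
    min_overlap: int = 6,
    error_rate: float = 0.1,
) -> str | None:
    """Truncate *sequence* at the leftmost adapter occurrence.

    An occurrence at position i is either the full adapter (when it fits)
    or a prefix of the adapter reaching the 3' terminus, of length >=
    *min_overlap*; in both cases up to ``floor(error_rate * matched_len)``
    mismatches are tolerated. Returns the insert (possibly empty) or None
    when no occurrence is found.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    n, m = len(sequence), len(adapter)
    for i in range(0, n - min_overlap + 1):
        k = min(m, n - i)
        max_mm = int(error_rate * k)
        mm = 0
        for a, b in zip(sequence[i : i + k], adapter[:k]):
            if a != b:
                mm += 1
                if mm > max_mm:
                    break
        else:
            return sequence[:i]
    return None


def strip_random_bases(sequence: str, n: int = 4) -> str | None:
    """Remove the n randomized bases from each end; None if too short."""
    if len(sequence) < 2 * n + 1:
        return None
    return sequence[n : len(sequence) - n]


def length_gate(sequence: str, min_len: int = 16, max_len: int = 28) -> bool:
    """Inclusive length bounds on the final insert."""
    return min_len <= len(sequence) <= max_len


def preprocess_fastq(
    in_path: str | Path,
    out_path: str | Path | None = None,
    adapter: str | None = DEFAULT_ADAPTER,
    randomized_bases: int = 4,
    min_len: int = 16,
    max_len: int = 28,
    min_overlap: int = 6,
    error_rate: float = 0.1,
) -> PreprocessStats:
    """Run the full cleaning chain on a FASTQ file (gzip transparent).

    When *out_path* is None only statistics are computed. Surviving reads
    are written with their original id and the quality substring matching
    the retained insert. ``adapter=None`` disables the adapter search (for
    re-processing already-cleaned files); pair it with
    ``randomized_bases=0`` and the operation is idempotent.
    """
    stats = PreprocessStats()
    out = _open_write(out_path) if out_path is not None else None
    try:
        for rid, seq, qual in _iter_fastq(in_path):
            stats.input_reads += 1
            if adapter is None:
                trimmed = seq
            else:
                trimmed = trim_adapter(seq, adapter, min_overlap, error_rate)
                if trimmed is None:
                    stats.discarded_no_adapter += 1
                    continue
                stats.adapter_found += 1
            insert = strip_random_bases(trimmed, randomized_bases)
            if insert is None or not length_gate(insert, min_len, max_len):
                stats.discarded_length += 1
                continue
            stats.passed_length += 1
            if out is not None:
                q = qual[randomized_bases : randomized_bases + len(insert)] if qual else "I" * len(insert)
                out.write(f"@{rid}\n{insert}\n+\n{q}\n")
    finally:
        if out is not None:
            out.close()
    stats.check()
    return stats


def _open_write(path: str | Path):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    return gzip.open(path, "wt") if path.suffix == ".gz" else open(path, "w")


def _iter_fastq(path: str | Path):
    """Minimal strict 4-line FASTQ reader; names the record on error."""
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        rec = 0
        while True:
            header = fh.readline()
            if not header:
                return
            seq = fh.readline().rstrip("\n")
            plus = fh.readline()
            qual = fh.readline().rstrip("\n")
            if not header.startswith("@") or not plus.startswith("+") or not seq:
                raise ParseError(f"malformed FASTQ record {rec} in {path}")
            if qual and len(qual) != len(seq):
                raise ParseError(f"quality/sequence length mismatch at record {rec} in {path}")
            yield header[1:].split()[0], seq, qual
            rec += 1
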