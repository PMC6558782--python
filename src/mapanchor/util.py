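"""Small shared helpers: sequence ops, exact search, atomic file writes, FASTA I/O."""

from __future__ import annotations

import os
import tempfile
from contextlib import contextmanager
from typing import Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_RC = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a plain nucleotide string."""
    return seq.translate(_RC)[::-1]


def find_all(haystack: str, needle: str) -> Iterator[int]:
    """Yield every 0-based start of ``needle`` in ``haystack`` (overlaps allowed)."""
    if not needle:
        return
    i = haystack.find(needle)
    while i != -1:
        yield i
        i = haystack.find(needle, i + 1)


@contextmanager
def atomic_write(path: str | os.PathLike, mode: str = "w"):
    """Write to a temp file in the target directory, rename into place on success."""
    path = os.fspath(path)
    d = os.path.dirname(os.path.abspath(path))
    os.makedirs(d, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=d, prefix=".tmp_", suffix="~")
    try:
        with os.fdopen(fd, mode) as fh:
            yield fh
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Load a FASTA file as an id -> uppercase sequence dict (order preserved)."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(os.fspath(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | os.PathLike, width: int = 80) -> None:
    with atomic_write(path) as fh:
        SeqIO.write(
            (SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()),
            fh,
            "fasta",
        )


class ConfigurationError(ValueError):
    """An invalid configuration value; the message names the offending field."""


class DependencyError(RuntimeError):
    """A pipeline stage was invoked before the stage that produces its inputs."""


class ParseError(ValueError):
    """A malformed input file; the message names the file and line."""
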