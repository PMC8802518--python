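"""Small shared helpers."""

from __future__ import annotations

import os
import tempfile
from contextlib import contextmanager

_RC = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def canonical(kmer: str) -> tuple[str, bool]:
    """Canonical form of a k-mer and whether the forward orientation won.

    Returns (min(kmer, revcomp(kmer)), is_forward).
    """
    rc = kmer.translate(_RC)[::-1]
    if kmer <= rc:
        return kmer, True
    return rc, False


@contextmanager
def atomic_write(path: str | os.PathLike, mode: str = "w"):
    """Write to a temp file in the target directory, rename on success."""
    path = os.fspath(path)
    d = os.path.dirname(path) or "."
    fd, tmp = tempfile.mkstemp(dir=d, prefix=".tmp-", suffix=os.path.basename(path))
    try:
        with os.fdopen(fd, mode) as fh:
            yield fh
        os.replace(tmp, path)
    except BaseException:
        try:
            os.unlink(tmp)
        except OSError:
            pass
        raise
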