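import numpy as np
import pandas as pd
import pytest

from tekit.intervals import GenomicInterval
from tekit.repeats import RepeatHit


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture
def two_group_labels():
    cols = ["ctrl.r1", "ctrl.r2", "ctrl.r3", "kd.r1", "kd.r2", "kd.r3"]
    return pd.Series({c: c.split(".")[0] for c in cols})


def random_hits(rng, n, chroms=("chr1", "chr2"), families=(("INTA-int", "INTALTR"), ("BINT-int", "BINTLTR2"))):
    """Randomized RepeatMasker hits for merge-oracle tests: internals and LTRs
    scattered with gaps straddling the 400 bp rule."""
    hits = []
    pos = {c: 1 for c in chroms}
    for i in range(n):
        chrom = chroms[int(rng.integers(len(chroms)))]
        strand = "+" if rng.random() < 0.5 else "-"
        internal, ltr = families[int(rng.integers(len(families)))]
        name = internal if rng.random() < 0.5 else ltr
        gap = int(rng.choice([0, 50, 200, 399, 400, 401, 500, 1200]))
        start = pos[chrom] + gap
        length = int(rng.integers(100, 2000))
        hits.append(
            RepeatHit(chrom=chrom, start=start, end=start + length - 1, strand=strand,
                      repeat_name=name, repeat_class_family="LTR/ERVK",
                      sw_score=int(rng.integers(300, 9000)), hit_id=f"h{i}")
        )
        pos[chrom] = start + length
    return hits


def random_intervals(rng, n, chroms=("chr1", "chr2"), span=1_000_000, max_len=5000, prefix="iv"):
    starts = rng.integers(0, span - max_len, size=n)
    lengths = rng.integers(1, max_len, size=n)
    which = rng.integers(0, len(chroms), size=n)
    return [
        GenomicInterval(chrom=chroms[w], start=int(s), end=int(s + l), name=f"{prefix}{i}")
        for i, (w, s, l) in enumerate(zip(which, starts, lengths))
    ]
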