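import numpy as np
import pytest

from ycontig.kmers import reverse_complement

ALPHABET = "ACGT"


def random_seq(rng: np.random.Generator, n: int, with_n: float = 0.0) -> str:
    bases = "ACGTN" if with_n else "ACGT"
    p = None
    if with_n:
        p = [(1 - with_n) / 4] * 4 + [with_n]
    return "".join(rng.choice(list(bases), size=n, p=p))


def brute_force_kmers(seq: str, k: int, canonical: bool = True) -> list[str]:
    """Independent window-enumeration oracle for k-merization."""
    seq = seq.upper()
    out = []
    for i in range(len(seq) - k + 1):
        w = seq[i:i + k]
        if any(b not in ALPHABET for b in w):
            continue
        if canonical:
            w = min(w, reverse_complement(w))
        out.append(w)
    return out


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def write_fasta_file(tmp_path):
    def _write(records, name="seqs.fa"):
        path = tmp_path / name
        with open(path, "w") as fh:
            for rid, seq in records:
                fh.write(f">{rid}\n{seq}\n")
        return str(path)
    return _write
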