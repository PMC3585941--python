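import numpy as np
import pytest

from oryzamir import pipeline, synth


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """One full pipeline run on the default synthetic study (seed 0)."""
    out = tmp_path_factory.mktemp("default_run")
    cfg = pipeline.RunConfig(outdir=str(out), seed=0,
                             synthetic=synth.SyntheticConfig(seed=0))
    return pipeline.run_all(cfg)


@pytest.fixture(scope="session")
def small_config():
    """A reduced study for determinism / byte-identity checks."""
    return synth.SyntheticConfig(
        genome_length=80_000, n_novel_hairpins=2,
        n_background_regions=30, n_background_sources=600,
        library_depths=(20_000,) * 4, seed=7)


def enumerate_mfe(seq, min_loop=3):
    """Independent folding oracle: exhaustively enumerate every nested
    structure (no pseudoknots, hairpin loops >= min_loop) and return the
    minimum total pair energy."""
    from oryzamir.fold import pair_energy
    seq = seq.upper().replace("T", "U")
    n = len(seq)

    def best(i, j):
        if j - i < min_loop + 1:
            return 0.0
        options = [best(i, j - 1)]  # j unpaired
        for k in range(i, j - min_loop):
            e = pair_energy(seq[k], seq[j])
            if e < 0:
                options.append(best(i, k - 1) + e + best(k + 1, j - 1))
        return min(options)

    return best(0, n - 1)


@pytest.fixture(scope="session")
def fold_oracle():
    return enumerate_mfe


def write_fastq(path, reads, qual_char="I"):
    with open(path, "w") as fh:
        for i, item in enumerate(reads):
            if isinstance(item, tuple):
                seq, qual = item
            else:
                seq, qual = item, qual_char * len(item)
            fh.write(f"@r{i}\n{seq}\n+\n{qual}\n")
    return path


@pytest.fixture
def fastq_writer():
    return write_fastq


@pytest.fixture
def rng():
    return np.random.default_rng(42)
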