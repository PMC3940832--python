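import pytest

from moabarcode.seqio import Alignment


@pytest.fixture
def tiny_alignment() -> Alignment:
    """Four clean 12 bp sequences anchored at the COI fragment start."""
    return Alignment(
        (
            ("s1", "ACGTACGTACGT"),
            ("s2", "ACGTACGTACGA"),
            ("s3", "ACGTACGTACAA"),
            ("s4", "GCGTACGTACAA"),
        ),
        ref_start=6996,
    )


@pytest.fixture
def write_fasta(tmp_path):
    def _write(records, name="aln.fasta"):
        path = tmp_path / name
        with open(path, "w") as fh:
            for sid, seq in records:
                fh.write(f">{sid}\n{seq}\n")
        return path

    return _write
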