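import pathlib

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow], deadline=None
)
settings.load_profile("ci")


@pytest.fixture
def write_fasta(tmp_path):
    """Write records to a temp FASTA file and return its path."""

    def _write(records: dict[str, str], name: str = "genome.fa") -> pathlib.Path:
        path = tmp_path / name
        path.write_text(
            "".join(f">{rid}\n{seq}\n" for rid, seq in records.items())
        )
        return path

    return _write


@pytest.fixture
def write_gff3(tmp_path):
    def _write(lines: list[str], name: str = "ann.gff3") -> pathlib.Path:
        path = tmp_path / name
        path.write_text("##gff-version 3\n" + "\n".join(lines) + "\n")
        return path

    return _write
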