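from pathlib import Path

import pytest
from hypothesis import HealthCheck, settings

from mitodel import simgen

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rcrs_like_ref():
    """Random 16,569 bp circular genome with rCRS-scaled region annotations."""
    return simgen.simulate_reference(16569, seed=11)


@pytest.fixture
def sam_file(tmp_path):
    """Write SAM text built from (qname, flag, rname, pos, mapq, cigar) rows."""

    def _write(rows, contigs=(("chrM", 16569),), name="reads.sam") -> Path:
        lines = ["@HD\tVN:1.6\tSO:unknown"]
        lines += [f"@SQ\tSN:{c}\tLN:{ln}" for c, ln in contigs]
        for qname, flag, rname, pos, mapq, cigar in rows:
            lines.append(
                f"{qname}\t{flag}\t{rname}\t{pos}\t{mapq}\t{cigar}\t*\t0\t0\t*\t*"
            )
        path = tmp_path / name
        path.write_text("\n".join(lines) + "\n")
        return path

    return _write
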