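import pytest
from hypothesis import HealthCheck, settings

from vitisnp.io import AccessionMeta, Dataset, MarkerAlignment

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_alignment(rows: dict[str, str], name: str = "M1") -> MarkerAlignment:
    length = len(next(iter(rows.values())))
    return MarkerAlignment(name, length, dict(rows))


def make_dataset(markers: list[MarkerAlignment], subgroups: dict[str, str] | None = None) -> Dataset:
    accs: list[str] = []
    for m in markers:
        for a in m.accession_ids:
            if a not in accs:
                accs.append(a)
    meta = [
        AccessionMeta(a, f"cv_{a}", (subgroups or {}).get(a, "Local"))
        for a in accs
    ]
    return Dataset(markers=markers, meta=meta)


@pytest.fixture
def toy_alignment() -> MarkerAlignment:
    # 10 columns: col3 has a gap, col6 an N, cols 1 and 8 are planted SNPs
    # (0-based positions 1 and 8), the rest monomorphic.
    return make_alignment(
        {
            "a1": "AAGT-CNGTA",
            "a2": "ACGT-CNGTA",
            "a3": "AAGTACNGCA",
        }
    )
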