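import math

import pytest
from hypothesis import HealthCheck, settings

from proteoalloc.io import ProteinRecord, SampleIntensity

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_records(ibaq_by_tag: dict[str, float | None],
                 mw_by_tag: dict[str, float] | None = None,
                 sample_id: str = "WT_LB_1") -> list[ProteinRecord]:
    """Toy protein records for one sample; MW defaults to 50 kDa."""
    return [
        ProteinRecord(
            protein_id=f"P_{tag}",
            locus_tag=tag,
            gene_name=tag.lower(),
            mol_weight=(mw_by_tag or {}).get(tag, 50_000.0),
            intensities={sample_id: SampleIntensity(ibaq=ibaq)},
        )
        for tag, ibaq in ibaq_by_tag.items()
    ]


def brute_force_sector_fraction(fractions: dict[str, float], members: set[str]) -> float:
    """Independent oracle: explicit membership loop over the allocation."""
    total = 0.0
    for tag, phi in fractions.items():
        if tag in members:
            total += phi
    return total


@pytest.fixture(scope="session")
def study_contrast():
    """Default study contrast (WT vs codY-null in LB), one fixed seed."""
    from proteoalloc.synthetic import SyntheticConfig, generate_condition_contrast

    return generate_condition_contrast(SyntheticConfig(seed=11))


def assert_close(a: float, b: float, tol: float = 1e-9) -> None:
    assert math.isfinite(a) and abs(a - b) <= tol, f"{a} != {b} (tol {tol})"
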