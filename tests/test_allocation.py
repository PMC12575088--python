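"""Mass fractions, sector aggregation and balance accounting."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from proteoalloc import allocation as alc
from proteoalloc.errors import DegenerateSampleError, ValidationError
from proteoalloc.io import SectorDefinition, SectorMode, parse_sample_id
from tests.conftest import brute_force_sector_fraction, make_records


class TestComputeMassFractions:
    def test_single_protein_gets_everything(self):
        alloc = alc.compute_mass_fractions(make_records({"A": 7.0}), "WT_LB_1")
        assert alloc.fractions == {"A": 1.0}

    def test_ibaq_mass_is_intensity_times_mol_weight(self):
        # iBAQ (10, 5) with MW (50, 100) kDa -> equal iBAQ mass -> equal phi
        records = make_records({"A": 10.0, "B": 5.0},
                               mw_by_tag={"A": 50_000.0, "B": 100_000.0})
        alloc = alc.compute_mass_fractions(records, "WT_LB_1")
        assert alloc.fractions == {"A": 0.5, "B": 0.5}

    def test_equal_mw_reduces_to_intensity_shares(self):
        alloc = alc.compute_mass_fractions(make_records({"A": 2.0, "B": 3.0, "C": 5.0}),
                                           "WT_LB_1")
        assert alloc.fractions == pytest.approx({"A": 0.2, "B": 0.3, "C": 0.5})

    def test_missing_intensities_counted_and_zeroed(self):
        alloc = alc.compute_mass_fractions(make_records({"A": 1.0, "B": None}), "WT_LB_1")
        assert alloc.n_missing == 1
        assert alloc.fractions["B"] == 0.0

    def test_all_missing_is_degenerate(self):
        with pytest.raises(DegenerateSampleError):
            alc.compute_mass_fractions(make_records({"A": None, "B": None}), "WT_LB_1")

    @given(st.lists(st.floats(min_value=1e-6, max_value=1e6), min_size=1, max_size=30),
           st.floats(min_value=1e-3, max_value=1e3))
    def test_normalization_and_scale_invariance(self, intensities, scale):
        """Fractions sum to 1 and are invariant to global intensity rescaling."""
        tags = {f"T{i}": v for i, v in enumerate(intensities)}
        base = alc.compute_mass_fractions(make_records(tags), "WT_LB_1")
        assert abs(math.fsum(base.fractions.values()) - 1.0) <= 1e-9
        scaled = alc.compute_mass_fractions(
            make_records({t: v * scale for t, v in tags.items()}), "WT_LB_1")
        for tag in tags:
            assert scaled.fractions[tag] == pytest.approx(base.fractions[tag], rel=1e-9)


class TestSectorFraction:
    def _alloc(self, n=12, seed=0):
        rng = np.random.default_rng(seed)
        tags = {f"T{i}": float(v) for i, v in enumerate(rng.uniform(0.1, 10.0, n))}
        return alc.compute_mass_fractions(make_records(tags), "WT_LB_1")

    def test_whole_proteome_sector_is_one(self):
        alloc = self._alloc()
        sector = SectorDefinition("all", frozenset(alloc.fractions))
        assert alc.sector_fraction(alloc, sector).value == pytest.approx(1.0, abs=1e-9)

    def test_disjoint_sector_is_zero(self):
        alloc = self._alloc()
        sector = SectorDefinition("none", frozenset({"BSU99990"}))
        result = alc.sector_fraction(alloc, sector)
        assert result.value == 0.0 and result.n_matched == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_membership_sum(self, seed):
        alloc = self._alloc(n=20, seed=seed)
        rng = np.random.default_rng(seed + 100)
        members = {t for t in alloc.fractions if rng.random() < 0.4} or {"T0"}
        sector = SectorDefinition("s", frozenset(members))
        expected = brute_force_sector_fraction(alloc.fractions, members)
        assert alc.sector_fraction(alloc, sector).value == pytest.approx(expected, abs=1e-12)


def _two_sector_records(phi_a: float, sample_id: str):
    """Two proteins with equal MW whose intensity shares are (phi_a, 1-phi_a)."""
    return make_records({"A1": phi_a, "B1": 1.0 - phi_a}, sample_id=sample_id)


class TestAggregateReplicates:
    scheme = alc.SectorScheme(
        partition=(SectorDefinition("alpha", frozenset({"A1"}), SectorMode.partition_member),),
    )

    def _table(self, phis):
        allocs, descs = [], []
        for i, phi in enumerate(phis, start=1):
            sid = f"WT_LB_{i}"
            allocs.append(alc.compute_mass_fractions(_two_sector_records(phi, sid), sid))
            descs.append(parse_sample_id(sid))
        return alc.aggregate_replicates(allocs, descs, self.scheme)

    def test_identical_replicates_have_zero_sd(self):
        table = self._table([0.3, 0.3, 0.3])
        row = table[table.sector == "alpha"].iloc[0]
        assert row.mean_fraction == pytest.approx(0.3) and row.sd_fraction == 0.0
        assert row.n_replicates == 3

    def test_mean_of_two_replicates(self):
        table = self._table([0.10, 0.12])
        row = table[table.sector == "alpha"].iloc[0]
        assert row.mean_fraction == pytest.approx(0.11)

    def test_other_sector_closes_partition(self):
        table = self._table([0.25, 0.25])
        by_sector = dict(zip(table.sector, table.mean_fraction))
        assert math.fsum(by_sector.values()) == pytest.approx(1.0, abs=1e-6)
        assert by_sector["other"] == pytest.approx(0.75)

    def test_overlapping_partition_sectors_rejected(self):
        with pytest.raises(ValidationError, match="overlap"):
            alc.SectorScheme(partition=(
                SectorDefinition("a", frozenset({"X", "Y"}), SectorMode.partition_member),
                SectorDefinition("b", frozenset({"Y"}), SectorMode.partition_member),
            ))


class TestBalanceAnalysis:
    def test_identical_conditions_give_zero_deltas(self):
        fr = {"r": 0.3, "aa": 0.1, "other": 0.6}
        report = alc.balance_analysis(fr, dict(fr), ["aa"], ["r"])
        assert all(d == 0.0 for d in report.delta.values())
        assert report.residual == 0.0

    def test_two_sector_toy_balances_exactly(self):
        report = alc.balance_analysis({"r": 0.6, "aa": 0.4}, {"r": 0.5, "aa": 0.5},
                                      ["aa"], ["r"])
        assert report.delta == {"r": pytest.approx(-0.1), "aa": pytest.approx(0.1)}
        assert report.residual == pytest.approx(0.0, abs=1e-12)

    def test_sector_mismatch_rejected(self):
        with pytest.raises(ValidationError, match="mismatch"):
            alc.balance_analysis({"r": 1.0}, {"q": 1.0}, ["r"], ["r"])

    def test_unknown_group_sector_rejected(self):
        with pytest.raises(ValidationError, match="unknown sector"):
            alc.balance_analysis({"r": 1.0}, {"r": 1.0}, ["nope"], ["r"])

    @given(st.integers(min_value=2, max_value=8), st.integers(min_value=0, max_value=10_000))
    def test_conservation_on_random_condition_pairs(self, n_sectors, seed):
        """Over a full partition the per-sector deltas always sum to zero."""
        rng = np.random.default_rng(seed)
        a = rng.dirichlet(np.ones(n_sectors))
        b = rng.dirichlet(np.ones(n_sectors))
        names = [f"s{i}" for i in range(n_sectors)]
        report = alc.balance_analysis(dict(zip(names, a)), dict(zip(names, b)),
                                      names[:1], names[1:2])
        assert abs(report.closure) <= 1e-6


class TestOverlayDecomposition:
    def _alloc(self):
        return alc.compute_mass_fractions(
            make_records({"A": 1.0, "B": 2.0, "C": 3.0, "D": 4.0}), "WT_LB_1")

    def test_overlay_superset_leaves_nothing_outside(self):
        alloc = self._alloc()
        partition = SectorDefinition("p", frozenset({"A", "B"}))
        overlay = SectorDefinition("o", frozenset({"A", "B", "C"}))
        inside, outside = alc.overlay_decomposition(alloc, overlay, partition)
        assert outside == 0.0 and inside == pytest.approx(0.3)

    def test_disjoint_overlay_contributes_nothing_inside(self):
        alloc = self._alloc()
        partition = SectorDefinition("p", frozenset({"A", "B"}))
        overlay = SectorDefinition("o", frozenset({"C", "D"}))
        inside, outside = alc.overlay_decomposition(alloc, overlay, partition)
        assert inside == 0.0 and outside == pytest.approx(0.3)

    def test_split_recomposes_partition_fraction(self, study_contrast):
        alloc = alc.compute_mass_fractions(study_contrast.records,
                                           study_contrast.samples[0].sample_id)
        overlay = study_contrast.gene_sets["cody_regulon"]
        partition = study_contrast.gene_sets["aa_biosynthesis"]
        inside, outside = alc.overlay_decomposition(alloc, overlay, partition)
        whole = alc.sector_fraction(alloc, partition).value
        assert inside + outside == pytest.approx(whole, abs=1e-9)
        assert inside > 0 and outside > 0
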