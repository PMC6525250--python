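import math

import numpy as np
import pytest

from symsurf import (
    BURIED,
    INTERFACE_CORE,
    OTHER,
    SURFACE,
    BuildSpec,
    PatchConfig,
    SasaRecord,
    StickinessScale,
    classify_region,
    complexed_and_unbound,
    derive_scale,
    environment_stickiness,
    make_cyclic,
)
from symsurf.errors import FormatError, InputError
from symsurf.stickiness import STANDARD_LETTERS


def literal_region_predicates(rasac, rasau, threshold=25.0):
    """Independent transcription of the region definitions, kept deliberately verbose."""
    delta = rasau - rasac
    if delta == pytest.approx(0.0, abs=1e-6) and rasac > threshold:
        return SURFACE
    if delta > 1e-6 and rasac < threshold and rasau > threshold:
        return INTERFACE_CORE
    if rasac < threshold:
        return BURIED
    return OTHER


class TestClassifyRegion:
    @pytest.mark.parametrize(
        "rasac,rasau,expected",
        [
            (30.0, 30.0, SURFACE),
            (10.0, 40.0, INTERFACE_CORE),
            (10.0, 10.0, BURIED),
            (40.0, 60.0, OTHER),  # interface rim: buried on binding but still exposed
            (25.0, 25.0, OTHER),  # exactly at threshold: strict comparisons exclude both
            (10.0, 20.0, BURIED),  # buried in both states despite positive delta
        ],
    )
    def test_examples(self, rasac, rasau, expected):
        assert classify_region(rasac, rasau) == expected

    def test_full_grid_matches_literal_transcription(self):
        values = np.arange(0.0, 100.5, 0.5)
        for rasac in values:
            for rasau in values:
                assert classify_region(rasac, rasau) == literal_region_predicates(
                    rasac, rasau
                ), (rasac, rasau)

    def test_partition_is_total_and_exclusive(self):
        rng = np.random.default_rng(41)
        labels = {SURFACE, INTERFACE_CORE, BURIED, OTHER}
        for rasac, rasau in rng.uniform(0, 100, size=(500, 2)):
            assert classify_region(rasac, rasau) in labels

    def test_out_of_range_rejected(self):
        with pytest.raises(InputError):
            classify_region(-1.0, 50.0)


class TestDeriveScale:
    def test_equal_frequencies_give_zero(self):
        counts = {aa: 10.0 for aa in STANDARD_LETTERS}
        scale = derive_scale(counts, counts)
        assert all(v == pytest.approx(0.0, abs=1e-12) for v in scale.values.values())

    def test_doubled_interface_frequency_gives_ln2(self):
        surface = {aa: 10.0 for aa in STANDARD_LETTERS}
        interface = dict(surface)
        interface["L"] = 20.0
        scale = derive_scale(surface, interface)
        # normalization shifts every value by the same constant; differences are exact
        assert scale["L"] - scale["A"] == pytest.approx(math.log(2.0), abs=1e-12)

    def test_antisymmetry_under_region_swap(self):
        rng = np.random.default_rng(42)
        surface = {aa: float(v) for aa, v in zip(STANDARD_LETTERS, rng.integers(5, 100, 20))}
        interface = {aa: float(v) for aa, v in zip(STANDARD_LETTERS, rng.integers(5, 100, 20))}
        forward = derive_scale(surface, interface)
        backward = derive_scale(interface, surface)
        for aa in STANDARD_LETTERS:
            assert forward[aa] == pytest.approx(-backward[aa], abs=1e-12)

    def test_pseudocount_applied_on_zero_counts(self):
        surface = {aa: 10.0 for aa in STANDARD_LETTERS}
        interface = {aa: 10.0 for aa in STANDARD_LETTERS}
        interface["W"] = 0.0
        scale = derive_scale(surface, interface)
        assert all(math.isfinite(v) for v in scale.values.values())
        assert scale["W"] < scale["A"]

    def test_empty_counts_rejected(self):
        with pytest.raises(InputError):
            derive_scale({}, {aa: 1.0 for aa in STANDARD_LETTERS})

    def test_scale_file_round_trip(self, tmp_path, random_scale):
        p = tmp_path / "scale.txt"
        random_scale.to_file(p)
        back = StickinessScale.from_file(p)
        for aa in STANDARD_LETTERS:
            assert back[aa] == pytest.approx(random_scale[aa], abs=1e-6)

    def test_incomplete_scale_rejected(self, tmp_path):
        p = tmp_path / "bad.txt"
        p.write_text("A 0.5\nG -0.2\n")
        with pytest.raises(InputError):
            StickinessScale.from_file(p)
        p.write_text("A\n")
        with pytest.raises(FormatError):
            StickinessScale.from_file(p)


class TestPatchConfig:
    def test_default_radius_is_analytic(self):
        patch = PatchConfig()
        assert patch.max_distance == pytest.approx(math.sqrt(400.0 / math.pi), abs=1e-12)
        assert round(patch.max_distance, 2) == 11.28

    def test_area_distance_consistency(self):
        patch = PatchConfig(patch_area=250.0)
        assert math.pi * patch.max_distance**2 == pytest.approx(250.0, abs=1e-9)


@pytest.fixture(scope="module")
def c3_with_sasa():
    asm, _ = make_cyclic(BuildSpec(n=3, chain_size=25, seed=43))
    from symsurf import SasaConfig

    return asm, complexed_and_unbound(asm, SasaConfig(sphere_points=240))


class TestEnvironmentStickiness:
    def test_constant_scale_returns_constant(self, c3_with_sasa, uniform_scale):
        asm, sasa = c3_with_sasa
        for rec in environment_stickiness(asm, sasa, uniform_scale):
            if rec.patch_size > 0:
                assert rec.sticky_patch == pytest.approx(0.42, abs=1e-12)
            else:
                assert rec.sticky_patch is None

    def test_value_within_scale_bounds(self, c3_with_sasa, random_scale):
        asm, sasa = c3_with_sasa
        lo, hi = min(random_scale.values.values()), max(random_scale.values.values())
        for rec in environment_stickiness(asm, sasa, random_scale):
            if rec.sticky_patch is not None:
                assert lo - 1e-12 <= rec.sticky_patch <= hi + 1e-12

    def test_center_exclusion(self, c3_with_sasa, random_scale):
        """Perturbing the center's own scale value must not change its patch value."""
        asm, sasa = c3_with_sasa
        base = {r.residue_key: r for r in environment_stickiness(asm, sasa, random_scale)}
        target_key, target_letter = None, None
        for res in asm.eligible_residues():
            rec = base.get(res.key)
            if rec is not None and rec.patch_size > 0:
                # pick a center whose own letter appears in no neighbor of itself
                letters_nearby = {
                    other.letter
                    for other in asm.eligible_residues()
                    if other.key != res.key
                    and np.linalg.norm(other.ca.coord - res.ca.coord) <= 11.2838
                }
                if res.letter not in letters_nearby:
                    target_key, target_letter = res.key, res.letter
                    break
        assert target_key is not None, "fixture should contain an isolated-letter center"
        perturbed_values = dict(random_scale.values)
        perturbed_values[target_letter] += 5.0
        perturbed = StickinessScale(perturbed_values, "perturbed")
        after = {
            r.residue_key: r for r in environment_stickiness(asm, sasa, perturbed)
        }
        assert after[target_key].sticky_patch == pytest.approx(
            base[target_key].sticky_patch, abs=1e-12
        )

    def test_buried_centers_get_no_record(self, c3_with_sasa, uniform_scale):
        asm, sasa = c3_with_sasa
        records = {r.residue_key for r in environment_stickiness(asm, sasa, uniform_scale)}
        buried = {
            r.residue_key
            for r in sasa
            if r.rASA_in_BU is not None and r.rASA_in_BU <= 25.0
        }
        assert not records & buried

    def test_patch_symmetry(self, c3_with_sasa, uniform_scale):
        """If i is a neighbor of j then j is a neighbor of i (same radius both ways)."""
        asm, sasa = c3_with_sasa
        rasac = {r.residue_key: r.rASA_in_BU for r in sasa}
        surface = [
            r
            for r in asm.eligible_residues()
            if rasac.get(r.key) is not None and rasac[r.key] > 25.0 and r.letter != "X"
        ]
        radius = PatchConfig().max_distance
        coords = {r.key: r.ca.coord for r in surface}
        keys = list(coords)
        neighbor_sets = {
            k: {
                other
                for other in keys
                if other != k and np.linalg.norm(coords[k] - coords[other]) <= radius
            }
            for k in keys
        }
        for k, nbrs in neighbor_sets.items():
            for other in nbrs:
                assert k in neighbor_sets[other]

    def test_isolated_surface_residue_has_empty_patch(self, uniform_scale):
        asm, _ = make_cyclic(BuildSpec(n=2, chain_size=12, radial_offset=200.0, seed=44))
        keys = [r.key for r in asm.eligible_residues()]
        # synthetic SASA: everything fully exposed, one residue moved out of range below
        sasa = [SasaRecord(k, 80.0, 80.0) for k in keys]
        lone = asm.chains[0].residues[0]
        lone.atoms[1].coord = lone.atoms[1].coord + np.array([0.0, 0.0, 500.0])
        records = {r.residue_key: r for r in environment_stickiness(asm, sasa, uniform_scale)}
        assert records[lone.key].patch_size == 0
        assert records[lone.key].sticky_patch is None
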