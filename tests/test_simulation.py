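"""Synthetic name pools, integrity experiments, phonebook attacks, sweeps."""

import numpy as np
import pytest

from pseudoid import (
    CodingConfig,
    InvalidNameError,
    SyntheticNameSpec,
    build_registry,
    collision_rate,
    config_for_space,
    encoding_success,
    generate_name_pool,
    load_name_list,
    phonebook_attack,
    sweep,
)
from pseudoid.normalization import normalize


def norm_key(name: str) -> str:
    return normalize(name, CodingConfig(L=1)).text


class TestLoadNameList:
    def test_order_blanks_and_duplicates(self, tmp_path):
        path = tmp_path / "names.txt"
        path.write_text("Ada Byron\n\n  Carl Friedrich Gauss  \nAda Byron\n\n")
        pool = load_name_list(path)
        assert pool.names == ["Ada Byron", "Carl Friedrich Gauss", "Ada Byron"]
        assert pool.source == str(path)

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "empty.txt"
        path.write_text("\n\n")
        with pytest.raises(InvalidNameError):
            load_name_list(path)


class TestGenerateNamePool:
    def test_seed_reproducibility(self):
        spec = SyntheticNameSpec(size=300, seed=9)
        assert generate_name_pool(spec).names == generate_name_pool(spec).names

    def test_different_seeds_differ(self):
        a = generate_name_pool(SyntheticNameSpec(size=100, seed=1))
        b = generate_name_pool(SyntheticNameSpec(size=100, seed=2))
        assert a.names != b.names

    def test_distinct_after_normalization_by_default(self):
        pool = generate_name_pool(SyntheticNameSpec(size=1000, seed=3))
        assert len({norm_key(n) for n in pool.names}) == 1000

    def test_exact_duplicate_count(self):
        pool = generate_name_pool(
            SyntheticNameSpec(size=1000, duplicate_rate=0.01, seed=4)
        )
        assert len(pool) == 1000
        assert len(pool.names) - len(set(pool.names)) == 10

    def test_phonetic_twins_are_twins(self):
        pool = generate_name_pool(
            SyntheticNameSpec(size=500, phonetic_twin_rate=0.02, seed=5)
        )
        # raw spellings all distinct, but 10 share a normalized form
        assert len(set(pool.names)) == 500
        assert len({norm_key(n) for n in pool.names}) == 490

    def test_infeasible_rates_rejected(self):
        with pytest.raises(InvalidNameError):
            SyntheticNameSpec(size=10, duplicate_rate=0.6, phonetic_twin_rate=0.5)


class TestCollisionRate:
    def test_single_item_cannot_collide(self, small_pool):
        res = collision_rate(small_pool, k=1, N=100, iterations=50, seed=0)
        assert res.collision_fraction == 0.0
        assert res.success_rate == 1.0

    def test_unit_space_forces_half_collisions(self, small_pool):
        res = collision_rate(small_pool, k=2, N=1, iterations=50, seed=0)
        assert res.collision_fraction == 0.5

    def test_oversized_sample_rejected(self, small_pool):
        with pytest.raises(InvalidNameError):
            collision_rate(small_pool, k=len(small_pool) + 1, N=100)

    @pytest.mark.parametrize("hash_fn", [0, 1, "double"])
    def test_hash_functions_agree_on_birthday_scale(self, small_pool, hash_fn):
        res = collision_rate(
            small_pool, k=50, N=500, hash_fn=hash_fn, iterations=400, seed=1
        )
        closed = 1 - 500 * (1 - (1 - 1 / 500) ** 50) / 50
        assert abs(res.collision_fraction - closed) <= 5 * res.collision_fraction_se


class TestEncodingSuccess:
    def test_single_participant_always_succeeds(self, small_pool):
        res = encoding_success(small_pool, k=1, N=10, iterations=20, seed=0)
        assert res.success_rate == 1.0
        assert res.hash_utilization == {0: 1.0}

    def test_unit_space_always_fails(self, small_pool):
        res = encoding_success(small_pool, k=2, N=1, iterations=20, seed=0)
        assert res.success_rate == 0.0

    def test_exact_duplicates_get_second_ids_and_hijack_lookups(self):
        """A duplicate add is not detected: it resolves like any collision.

        The original participant occupies only their default-hash slot, so
        the duplicate is assigned a distinct alternative ID — and because
        the attached validation code is computed from the *same* name, the
        original's subsequent lookups are redirected to the duplicate's
        ID.  This is the integrity hazard of re-adding a participant,
        which by design rests with the researcher.
        """
        # the whole pool is sampled every iteration, so every run contains
        # the exact duplicate pairs
        pool = generate_name_pool(
            SyntheticNameSpec(size=10, duplicate_rate=0.2, seed=6)
        )
        res = encoding_success(pool, k=10, N=100_000, iterations=30, seed=0)
        assert res.success_rate == 1.0  # every duplicate found a free slot
        assert res.all_registries_valid
        # each of the 2 duplicates per run redirects its original's lookup
        assert res.lookup_mismatch_count == 2 * 30

    def test_utilization_sums_to_one_and_registries_valid(self, small_pool):
        res = encoding_success(small_pool, k=40, N=400, iterations=200, seed=2)
        assert res.all_registries_valid
        assert sum(res.hash_utilization.values()) == pytest.approx(1.0)
        assert res.hash_utilization[0] > 0.9

    def test_monotonic_in_sample_size_and_space(self, small_pool):
        rates_k = [
            encoding_success(small_pool, k=k, N=100, iterations=400, seed=3).success_rate
            for k in (20, 50, 80)
        ]
        assert rates_k == sorted(rates_k, reverse=True)
        rates_n = [
            encoding_success(small_pool, k=60, N=n, iterations=400, seed=3).success_rate
            for n in (80, 200, 1000)
        ]
        assert rates_n == sorted(rates_n)


class TestPhonebookAttack:
    def test_conservation_and_self_hits(self, small_pool):
        config, registry, idx = build_registry(small_pool, k=50, N=500, seed=4)
        report = phonebook_attack(config, registry, small_pool)
        assert report.hits_per_slot.sum() == len(small_pool)
        assert report.mean_hits_per_space_slot == len(small_pool) / 500
        # participants hit their own IDs: none rejectable among their slots
        assert report.min_hits >= 1
        assert (
            report.rejectable_fraction
            + report.hits_per_slot[sorted(registry.ids)].sum() / len(small_pool)
            == pytest.approx(1.0)
        )

    def test_pool_equal_to_participants_rejects_nothing(self, small_pool):
        from pseudoid import NamePool

        config, registry, idx = build_registry(small_pool, k=30, N=300, seed=5)
        participants = NamePool([small_pool[i] for i in idx], source="participants")
        report = phonebook_attack(config, registry, participants)
        assert report.rejectable_fraction == 0.0
        assert report.min_hits >= 1

    def test_attack_uses_full_lookup_semantics(self, small_pool):
        # register into a tight space so attachments certainly exist
        config, registry, idx = build_registry(small_pool, k=30, N=60, seed=6)
        assert registry.attachments, "expected collisions in a tight space"
        from pseudoid import NamePool, lookup

        participants = [small_pool[i] for i in idx]
        report = phonebook_attack(
            config, registry, NamePool(participants, source="participants")
        )
        assert report.hits_per_slot.sum() == len(participants)
        # every participant's looked-up slot registered a hit
        for name in participants:
            assert report.hits_per_slot[lookup(name, config, registry)] >= 1


class TestSweep:
    def test_grid_shape_and_reproducibility(self, small_pool):
        table = sweep([5, 10], [50, 100], small_pool, iterations=30, seed=1)
        assert set(table["k"]) == {5, 10}
        assert set(table["N"]) == {50, 100}
        per_condition = table.groupby(["k", "N"]).size()
        assert (per_condition >= 4).all()
        again = sweep([5, 10], [50, 100], small_pool, iterations=30, seed=1)
        assert table.equals(again)

    def test_empty_grid(self, small_pool):
        table = sweep([], [], small_pool, iterations=10, seed=0)
        assert table.empty

    def test_attack_metrics_and_csv_output(self, small_pool, tmp_path):
        out = tmp_path / "sweep.csv"
        table = sweep(
            [10], [100], small_pool, iterations=20, seed=2,
            run_attack=True, output=out,
        )
        metrics = set(table["metric"])
        assert {"success_rate", "k_anonymity", "mean_hits_per_space_slot"} <= metrics
        assert out.exists()
        mean_row = table[table["metric"] == "mean_hits_per_space_slot"]
        assert mean_row["value"].iloc[0] == len(small_pool) / 100


def test_config_for_space_exact_sizes():
    assert config_for_space(1000).N == 1000
    assert config_for_space(7).N == 7
    assert config_for_space(103_472).N == 103_472


def test_plots_render_to_files(small_pool, tmp_path):
    pytest.importorskip("matplotlib")
    from pseudoid.plotting import plot_anonymity, plot_success_rates

    table = sweep([5, 10], [100], small_pool, iterations=10, seed=8, run_attack=True)
    p1, p2 = tmp_path / "success.png", tmp_path / "anonymity.png"
    plot_success_rates(table, str(p1))
    plot_anonymity(table[table["k"] == 10], str(p2))
    assert p1.stat().st_size > 0 and p2.stat().st_size > 0
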