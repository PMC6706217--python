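"""Determinism, structure and programmed effects of the transect generator."""

import collections

import numpy as np
import pandas as pd
import pytest

from waxtransect import (
    SpeciesModel,
    SyntheticConfig,
    compute_metrics,
    default_config,
    generate_dataset,
    generate_profiles,
    generate_sites,
    odd_even_preference,
    spearman,
)
from waxtransect.errors import ValidationError


def one_species_config(seed=0, **species_overrides):
    defaults = dict(name="Test sp.", site_occupancy=(0.0, 1e6))
    defaults.update(species_overrides)
    return SyntheticConfig(
        species=(SpeciesModel(**defaults),), replicate_spec=(), n_outliers=0, seed=seed
    )


class TestSites:
    def test_default_transect_shape(self):
        sites = generate_sites(default_config(seed=5))
        assert len(sites) == 14
        mats = [s.mat_c for s in sites]
        # programmed endpoints 21.6 and 7.2 C, within the site noise (SD 0.3)
        assert max(mats) - min(mats) == pytest.approx(14.4, abs=1.5)
        assert all(0 <= s.rh_pct <= 100 for s in sites)

    def test_same_seed_is_bit_identical(self):
        assert generate_sites(default_config(seed=9)) == generate_sites(default_config(seed=9))

    def test_zero_noise_makes_mat_exactly_linear(self):
        cfg = default_config(seed=1, mat_noise_sd_c=0.0, rh_noise_sd_pct=0.0,
                             map_noise_sd_mm=0.0)
        sites = generate_sites(cfg)
        lo = cfg.elevation_range_m[0]
        for s in sites:
            expected = cfg.mat_at_min_elev_c - cfg.lapse_rate_c_per_m * (s.elevation_m - lo)
            assert s.mat_c == pytest.approx(expected, abs=1e-12)

    def test_covariates_are_mutually_rank_correlated(self):
        sites = generate_sites(default_config(seed=3))
        mat = [s.mat_c for s in sites]
        rh = [s.rh_pct for s in sites]
        mp = [s.map_mm for s in sites]
        for a, b in ((mat, rh), (mat, mp), (rh, mp)):
            assert abs(spearman(a, b).rs) > 0.85

    def test_degenerate_elevation_range_rejected(self):
        with pytest.raises(ValidationError):
            SyntheticConfig(elevation_range_m=(1000.0, 1000.0))


class TestProfiles:
    def test_no_effect_no_noise_gives_identical_compositions(self):
        cfg = one_species_config(noise_cv=0.0, beta={})
        sites = generate_sites(cfg)
        profiles, _ = generate_profiles(cfg, sites)
        rels = {
            p.sample_id: tuple(v / p.total_concentration for v in
                               (p.conc[c] for c in sorted(p.conc)))
            for p in profiles
        }
        first = next(iter(rels.values()))
        for rel in rels.values():
            assert rel == pytest.approx(first, rel=1e-9)

    def test_oep_factor_one_gives_no_alternation(self):
        cfg = one_species_config(noise_cv=0.0, oep_factor=1.0, c23_boost=1.0)
        sites = generate_sites(cfg)
        profiles, _ = generate_profiles(cfg, sites)
        assert not any(odd_even_preference(profiles[0]).values())

    def test_default_species_show_oep_with_c23_anomalies(self):
        ds = generate_dataset(default_config(seed=2))
        anomalous = 0
        for species in {p.species for p in ds.profiles}:
            p = next(q for q in ds.profiles if q.species == species)
            flags = odd_even_preference(p)
            assert all(flags[n] for n in (27, 29, 31))  # core chains always OEP
            if not flags[23]:
                anomalous += 1
        assert anomalous >= 3  # several species carry the C23 anomaly

    def test_programmed_temperature_response_recovered(self):
        cfg = one_species_config(seed=11, beta={"mat_c": 0.15})
        sites = generate_sites(cfg)
        profiles, _ = generate_profiles(cfg, sites)
        records = compute_metrics(profiles)
        mat = {s.site_id: s.mat_c for s in sites}
        res = spearman([mat[r.site_id] for r in records], [r.acl for r in records])
        assert res.rs > 0.5 and res.p < 0.01

    def test_empty_occupancy_warns_and_skips(self, caplog):
        import logging

        sp = SpeciesModel(name="Nowhere sp.", site_occupancy=(9000.0, 9999.0))
        cfg = SyntheticConfig(species=(sp,), replicate_spec=(), n_outliers=0)
        sites = generate_sites(cfg)
        with caplog.at_level(logging.WARNING):
            profiles, _ = generate_profiles(cfg, sites)
        assert profiles == [] and "Nowhere sp." in caplog.text


class TestDataset:
    def test_default_dataset_structure(self):
        ds = generate_dataset(default_config(seed=0))
        species = {p.species for p in ds.profiles}
        assert len(species) == 6
        base = [p for p in ds.profiles if "-r" not in p.sample_id]
        assert 60 <= len(base) <= 120
        assert len(base) >= 80
        # 14 replicate measurements across 6 groups, as 3+3+2+2+2+2
        groups = collections.Counter(
            p.replicate_group for p in ds.profiles if p.replicate_group
        )
        assert sorted(groups.values(), reverse=True) == [3, 3, 2, 2, 2, 2]
        ids = [p.sample_id for p in ds.profiles]
        assert len(ids) == len(set(ids))

    def test_truth_table_lists_exactly_the_injected_outliers(self):
        cfg = default_config(seed=4)
        ds = generate_dataset(cfg)
        listed = set(ds.truth[ds.truth["kind"] == "outlier"]["name"])
        assert len(listed) == cfg.n_outliers
        # outlier samples exist and their C31 was crushed relative to siblings
        by_id = {p.sample_id: p for p in ds.profiles}
        for sid in listed:
            p = by_id[sid]
            siblings = [
                q for q in ds.profiles
                if q.species == p.species and q.site_id == p.site_id
                and q.sample_id != sid
            ]
            assert p.conc[31] < 0.5 * min(q.conc[31] for q in siblings)

    def test_seed_changes_noise_not_structure(self):
        a = generate_dataset(default_config(seed=1))
        b = generate_dataset(default_config(seed=2))
        assert {p.sample_id for p in a.profiles if "-r" not in p.sample_id} == {
            p.sample_id for p in b.profiles if "-r" not in p.sample_id
        }
        assert any(
            pa.conc != pb.conc
            for pa, pb in zip(sorted(a.profiles, key=lambda p: p.sample_id),
                              sorted(b.profiles, key=lambda p: p.sample_id))
            if pa.sample_id == pb.sample_id
        )

    def test_full_determinism_of_written_tables(self, tmp_path):
        p1 = generate_dataset(default_config(seed=6)).write(tmp_path / "a", seed=6)
        p2 = generate_dataset(default_config(seed=6)).write(tmp_path / "b", seed=6)
        for key in p1:
            assert p1[key].read_bytes() == p2[key].read_bytes()
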