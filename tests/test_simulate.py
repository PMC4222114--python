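import pytest

from vitisnp.alphabet import iub_for_alleles
from vitisnp.discovery import discover_snps
from vitisnp.errors import SimulationConfigError
from vitisnp.genotyping import build_genotype_matrix, collapse_genotypes
from vitisnp.simulate import SimConfig, simulate, write_simulation


def small_cfg(**kw) -> SimConfig:
    base = dict(
        seed=0,
        marker_lengths=[250, 150],
        n_cultivars=12,
        n_synonym_pairs=1,
        n_mislabels=1,
        n_outgroups=2,
        n_clonal_cultivars=2,
    )
    base.update(kw)
    return SimConfig(**base)


class TestDeterminism:
    def test_same_seed_byte_identical_files(self, tmp_path):
        p1 = write_simulation(simulate(small_cfg(seed=7)), tmp_path / "r1")
        p2 = write_simulation(simulate(small_cfg(seed=7)), tmp_path / "r2")
        for key in p1:
            assert p1[key].read_bytes() == p2[key].read_bytes()

    def test_different_seed_differs(self):
        d1 = simulate(small_cfg(seed=1)).dataset
        d2 = simulate(small_cfg(seed=2)).dataset
        assert d1.markers[0].sequences != d2.markers[0].sequences


class TestDegenerateAndInvalid:
    def test_single_cultivar_no_polymorphism(self):
        cfg = SimConfig(
            seed=0, marker_lengths=[100], n_cultivars=1, n_synonym_pairs=0,
            n_mislabels=0, n_outgroups=0, ingroup_snp_rate=0.0,
            n_clonal_cultivars=0,
        )
        res = simulate(cfg)
        ds = res.dataset
        disc = discover_snps(ds)
        assert disc.n_snps == 0
        profile = build_genotype_matrix(disc.all_sites, ds.accession_ids)
        assert len(collapse_genotypes(profile)) == 1

    @pytest.mark.parametrize(
        "kw",
        [
            dict(n_synonym_pairs=10),  # 2*10 > 12 cultivars
            dict(het_fraction=1.5),
            dict(marker_lengths=[0]),
            dict(n_outgroups=99),
            dict(n_cultivars=0),
        ],
    )
    def test_unsatisfiable_config_rejected(self, kw):
        with pytest.raises(SimulationConfigError):
            simulate(small_cfg(**kw))


class TestGroundTruth:
    def test_het_sites_rendered_as_iub_codes(self):
        res = simulate(small_cfg(seed=3))
        ds = res.dataset
        for cv, codes in res.cultivar_codes.items():
            accs = [m.accession_id for m in ds.meta if m.cultivar_name == cv and m.clone_of is None]
            if not accs:
                continue
            acc = accs[0]
            for (marker, pos), code in codes.items():
                ref, alt = res.site_alleles[(marker, pos)]
                symbol = ds.marker(marker).sequences[acc][pos]
                if code == 1:
                    assert symbol == iub_for_alleles((ref, alt))
                elif code == 0:
                    assert symbol == ref
                else:
                    assert symbol == alt

    def test_partition_rederivable_from_sequences(self):
        res = simulate(small_cfg(seed=5))
        concat = res.dataset.concatenated()
        groups: dict[str, set] = {}
        for a, s in concat.items():
            groups.setdefault(s, set()).add(a)
        assert sorted(map(sorted, groups.values())) == sorted(
            map(sorted, res.truth.partition)
        )

    def test_clones_share_identical_sequences(self):
        res = simulate(small_cfg(seed=6))
        ds = res.dataset
        clones = [m for m in ds.meta if m.clone_of and not any(
            mm[0] == m.accession_id for mm in res.truth.mislabels
        )]
        assert clones, "config should produce clonal accessions"
        concat = ds.concatenated()
        by_id = ds.meta_by_id
        for c in clones:
            original = next(
                m.accession_id
                for m in ds.meta
                if m.cultivar_name == c.clone_of and m.clone_of is None
            )
            assert concat[c.accession_id] == concat[original]

    def test_truth_json_roundtrip(self, tmp_path):
        from vitisnp.simulate import GroundTruth

        res = simulate(small_cfg(seed=8))
        t2 = GroundTruth.from_json(res.truth.to_json())
        assert t2 == res.truth


class TestNoiseColumns:
    def test_planted_ambiguity_and_gap_columns_audited(self):
        cfg = small_cfg(seed=9, ambiguous_site_rate=0.05, indel_site_rate=0.05)
        ds = simulate(cfg).dataset
        disc = discover_snps(ds)
        total_amb = sum(a.ambiguous for a in disc.audits.values())
        total_indel = sum(a.indel for a in disc.audits.values())
        assert total_amb > 0 and total_indel > 0

    def test_outgroup_divergence_within_tolerance(self):
        from vitisnp.distances import k2p_matrix
        import numpy as np

        res = simulate(small_cfg(seed=10, marker_lengths=[800, 800]))
        ds = res.dataset
        dm = k2p_matrix(ds.concatenated())
        og = set(res.truth.outgroups)
        ig = [a for a in dm.labels if a not in og]
        vals = [dm.get(o, i) for o in og for i in ig]
        mean = float(np.mean(vals))
        assert 0.14 <= mean <= 0.26  # within +/-30% of the 0.2 target
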