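"""Subclone assignment, mixture draws and expected allele frequencies."""

import numpy as np
import pytest
from scipy import stats

from tumorbench.mixing import (
    AdmixedSample,
    CloneMixture,
    DEFAULT_ADMIXTURE_LEVELS,
    MATERNAL,
    PATERNAL,
    SubcloneAssignment,
    assign_subclones,
    dilute_af,
    draw_mixture,
    expected_af,
    make_admixture_series,
    mix_two_genomes,
)
from tumorbench.variants import Origin, Variant, VariantClass


def somatic_snv(vid, pos=100):
    return Variant(vid, "chr1", pos, "A", "T", VariantClass.SNV, Origin.SOMATIC)


class TestAssignSubclones:
    def test_inclusion_prob_one_puts_every_variant_everywhere(self):
        variants = [somatic_snv(f"v{i}", 10 * i + 10) for i in range(20)]
        assignment = assign_subclones(variants, n_per_lineage=5, inclusion_prob=1.0, seed=3)
        for v in variants:
            assert len(assignment.members(v.id)) == 10

    def test_every_variant_carried_by_at_least_one_genome(self):
        variants = [somatic_snv(f"v{i}", 10 * i + 10) for i in range(500)]
        assignment = assign_subclones(variants, n_per_lineage=2, inclusion_prob=0.1, seed=9)
        assert all(len(assignment.members(v.id)) >= 1 for v in variants)

    def test_mean_membership_matches_truncated_binomial(self):
        """Zero-truncated Binomial(10, 0.5) mean within 3 s.e. at 10,000 variants."""
        n, p, n_var = 10, 0.5, 10_000
        variants = [somatic_snv(f"v{i}", 10 * i + 10) for i in range(n_var)]
        assignment = assign_subclones(variants, n_per_lineage=5, inclusion_prob=p, seed=42)
        sizes = np.array([len(assignment.members(v.id)) for v in variants])
        k = np.arange(n + 1)
        pmf = stats.binom.pmf(k, n, p)
        pmf[0] = 0.0
        pmf /= pmf.sum()
        mean = (k * pmf).sum()
        sd = np.sqrt(((k - mean) ** 2 * pmf).sum())
        assert mean == pytest.approx(n * p / (1 - (1 - p) ** n))
        assert abs(sizes.mean() - mean) < 3 * sd / np.sqrt(n_var)

    def test_same_seed_identical_membership(self):
        variants = [somatic_snv(f"v{i}", 10 * i + 10) for i in range(100)]
        a1 = assign_subclones(variants, 5, 0.5, seed=7)
        a2 = assign_subclones(variants, 5, 0.5, seed=7)
        assert a1.membership == a2.membership

    def test_empty_list_allowed(self):
        assert assign_subclones([], 5, 0.5, seed=1).membership == {}

    def test_sidecar_round_trip(self):
        variants = [somatic_snv(f"v{i}", 10 * i + 10) for i in range(30)]
        a = assign_subclones(variants, 3, 0.4, seed=2)
        assert SubcloneAssignment.from_json(a.to_json()).membership == a.membership


class TestDrawMixture:
    def test_single_genome_gets_weight_one(self):
        m = draw_mixture(n_per_lineage=1, seed=0)
        assert m.maternal_weights == (1.0,)
        assert m.paternal_weights == (1.0,)

    def test_weights_normalized_across_seeds(self):
        for seed in range(200):
            m = draw_mixture(5, seed=seed)
            assert abs(sum(m.maternal_weights) - 1.0) < 1e-12
            assert abs(sum(m.paternal_weights) - 1.0) < 1e-12

    def test_flat_dirichlet_symmetry(self):
        """Each weight averages 1/n over many draws (Dirichlet(1) marginal)."""
        n, draws = 5, 10_000
        acc = np.zeros(n)
        for seed in range(draws):
            acc += draw_mixture(n, seed=seed).maternal_weights
        means = acc / draws
        # marginal is Beta(1, n-1): sd = sqrt((n-1)/(n^2*(n+1)))
        se = np.sqrt((n - 1) / (n**2 * (n + 1)) / draws)
        assert np.all(np.abs(means - 1 / n) < 4 * se)


def make_sample(weights_m, weights_p, admixture):
    mixture = CloneMixture(maternal_weights=tuple(weights_m), paternal_weights=tuple(weights_p))
    return AdmixedSample(mixture=mixture, admixture=admixture, label=f"a{admixture}")


class TestExpectedAF:
    def test_dilution_of_clonal_30_percent_variant(self):
        """A 30% tumor-AF somatic variant reads at 3% under 90% admixture."""
        assert dilute_af(0.30, 0.9, control_af=0.0) == pytest.approx(0.03)

    def test_expected_af_full_path_reproduces_dilution(self):
        # maternal genome 0 (weight 0.6) carries the variant: AF_tumor = 0.3
        v = somatic_snv("s1")
        assignment = SubcloneAssignment(
            n_per_lineage=5, membership={"s1": frozenset({(MATERNAL, 0)})}
        )
        sample = make_sample((0.6, 0.1, 0.1, 0.1, 0.1), (0.2,) * 5, admixture=0.9)
        assert expected_af(v, assignment, sample) == pytest.approx(0.03)

    def test_germline_het_invariant_under_admixture(self):
        v = Variant("g1", "chr1", 5, "C", "G", VariantClass.SNV, Origin.GERMLINE)
        assignment = SubcloneAssignment(n_per_lineage=5, membership={})
        for a in (0.0, 0.3, 0.9):
            sample = make_sample((0.2,) * 5, (0.2,) * 5, a)
            assert expected_af(v, assignment, sample, control_af=0.5) == pytest.approx(0.5)

    def test_subclonal_maternal_pair_against_monte_carlo(self):
        """Closed form vs 10^6 haplotype draws (variant in maternal genomes 0, 1)."""
        v = somatic_snv("s1")
        members = frozenset({(MATERNAL, 0), (MATERNAL, 1)})
        assignment = SubcloneAssignment(n_per_lineage=5, membership={"s1": members})
        wm = (0.4, 0.3, 0.1, 0.1, 0.1)
        sample = make_sample(wm, (0.2,) * 5, admixture=0.0)
        closed = expected_af(v, assignment, sample)
        assert closed == pytest.approx(0.35)

        rng = np.random.default_rng(123)
        n = 1_000_000
        lineage_is_maternal = rng.random(n) < 0.5
        genome = rng.choice(5, size=n, p=wm)
        carries = lineage_is_maternal & np.isin(genome, [0, 1])
        mc = carries.mean()
        se = np.sqrt(closed * (1 - closed) / n)
        assert abs(mc - closed) < 3 * se

    def test_random_configurations_against_monte_carlo(self):
        """Closed-form AF agrees with haplotype-sampling simulation."""
        rng = np.random.default_rng(77)
        for _ in range(20):
            n_per = int(rng.integers(1, 6))
            wm = rng.dirichlet(np.ones(n_per))
            wp = rng.dirichlet(np.ones(n_per))
            members = frozenset(
                (lin, i)
                for lin in (MATERNAL, PATERNAL)
                for i in range(n_per)
                if rng.random() < 0.5
            ) or frozenset({(MATERNAL, 0)})
            a = float(rng.uniform(0, 0.95))
            assignment = SubcloneAssignment(n_per_lineage=n_per, membership={"s1": members})
            sample = make_sample(tuple(wm), tuple(wp), round(a, 6))
            closed = expected_af(somatic_snv("s1"), assignment, sample)

            n = 200_000
            maternal = rng.random(n) < 0.5
            gm = rng.choice(n_per, size=n, p=wm)
            gp = rng.choice(n_per, size=n, p=wp)
            carries = np.where(
                maternal,
                np.isin(gm, [i for lin, i in members if lin == MATERNAL]),
                np.isin(gp, [i for lin, i in members if lin == PATERNAL]),
            )
            tumor_draw = rng.random(n) >= a  # fragment comes from tumor material
            mc = (carries & tumor_draw).mean()
            se = max(np.sqrt(closed * (1 - closed) / n), 1e-9)
            assert abs(mc - closed) < 4 * se

    def test_monotone_decreasing_in_admixture_for_somatic(self):
        v = somatic_snv("s1")
        assignment = SubcloneAssignment(
            n_per_lineage=5, membership={"s1": frozenset({(MATERNAL, 0), (PATERNAL, 2)})}
        )
        afs = [
            expected_af(v, assignment, make_sample((0.2,) * 5, (0.2,) * 5, a))
            for a in DEFAULT_ADMIXTURE_LEVELS
        ]
        assert all(x > y for x, y in zip(afs, afs[1:]))

    def test_unknown_somatic_variant_fatal(self):
        assignment = SubcloneAssignment(n_per_lineage=5, membership={})
        sample = make_sample((0.2,) * 5, (0.2,) * 5, 0.1)
        with pytest.raises(KeyError):
            expected_af(somatic_snv("ghost"), assignment, sample, control_af=0.0)


class TestAdmixtureSeries:
    def test_default_series_has_ten_samples(self):
        m = draw_mixture(5, seed=0)
        samples = make_admixture_series(m)
        assert len(samples) == 10
        assert [s.admixture for s in samples] == [round(0.1 * i, 1) for i in range(10)]

    def test_single_level(self):
        samples = make_admixture_series(draw_mixture(5, seed=0), levels=[0.0])
        assert len(samples) == 1 and samples[0].admixture == 0.0

    def test_half_admixture_halves_somatic_af(self):
        v = somatic_snv("s1")
        assignment = SubcloneAssignment(
            n_per_lineage=5, membership={"s1": frozenset({(MATERNAL, 1)})}
        )
        m = draw_mixture(5, seed=4)
        s0 = AdmixedSample(m, 0.0, "a0")
        s50 = AdmixedSample(m, 0.5, "a50")
        assert expected_af(v, assignment, s50) == pytest.approx(0.5 * expected_af(v, assignment, s0))

    def test_duplicate_or_decreasing_levels_fatal(self):
        m = draw_mixture(5, seed=0)
        with pytest.raises(ValueError):
            make_admixture_series(m, levels=[0.1, 0.1])
        with pytest.raises(ValueError):
            make_admixture_series(m, levels=[0.5, 0.2])


class TestMixTwoGenomes:
    def test_het_only_in_minor_sample(self):
        a = {}
        b = {("chr1", 100, "A", "T"): 0.5}
        truth = mix_two_genomes(a, b, ratio=7 / 8)
        assert truth.records[0].expected_af == pytest.approx(7 / 16)

    def test_hom_in_both_is_clonal(self):
        key = ("chr1", 10, "G", "C")
        truth = mix_two_genomes({key: 1.0}, {key: 1.0}, ratio=0.3)
        assert truth.records[0].expected_af == pytest.approx(1.0)

    def test_even_mixture_of_hets_is_half(self):
        key = ("chr1", 10, "G", "C")
        truth = mix_two_genomes({key: 0.5}, {key: 0.5}, ratio=0.5)
        assert truth.records[0].expected_af == pytest.approx(0.5)

    def test_afs_are_discrete_multiples(self):
        r = 7 / 8
        a = {("chr1", 10, "A", "T"): 0.5, ("chr1", 20, "C", "G"): 1.0}
        b = {("chr1", 20, "C", "G"): 0.5, ("chr1", 30, "G", "A"): 1.0}
        truth = mix_two_genomes(a, b, ratio=r)
        for rec in truth.records:
            # every AF decomposes as i*(1-r)/2 + j*r/2 with i, j in {0, 1, 2}
            found = any(
                abs(rec.expected_af - (i * (1 - r) / 2 + j * r / 2)) < 1e-12
                for i in range(3)
                for j in range(3)
            )
            assert found

    def test_conflicting_ref_alleles_fatal(self):
        a = {("chr1", 10, "A", "T"): 0.5}
        b = {("chr1", 10, "G", "C"): 0.5}
        with pytest.raises(ValueError, match="conflicting ref"):
            mix_two_genomes(a, b, ratio=0.5)
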