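"""Phantom generator: determinism, HU/label consistency, topology, cohorts."""

from dataclasses import replace

import numpy as np
import pytest
from scipy import ndimage

from musclemap.phantom import (
    AIR_HU,
    PhantomSpec,
    PhantomSpecError,
    generate_cohort,
    generate_phantom,
    generate_phantom_sample,
    stratified_split,
)


def test_generation_is_deterministic():
    a_img, a_lab = generate_phantom(PhantomSpec(), 7)
    b_img, b_lab = generate_phantom(PhantomSpec(), 7)
    np.testing.assert_array_equal(a_img.values, b_img.values)
    np.testing.assert_array_equal(a_lab.classes, b_lab.classes)


def test_label_legend_and_all_classes_present(small_spec):
    _, lab = generate_phantom(small_spec, 3)
    present = set(np.unique(lab.classes))
    assert present == {0, 1, 2}


def test_muscle_pixels_carry_lean_tissue_hu(clean_spec):
    """Without pockets/noise/blur, every Muscle-labeled pixel must lie in
    the lean-muscle interval the generator is parameterized with."""
    for seed in (0, 1, 2):
        img, lab = generate_phantom(clean_spec, seed)
        muscle_hu = img.values[lab.classes == 1]
        lo, hi = clean_spec.muscle_hu_range
        assert muscle_hu.min() >= lo and muscle_hu.max() <= hi


def test_background_label_hu_consistency(clean_spec):
    """Outside the body everything is air; with edema disabled no
    Background pixel may fall in the muscle HU range (subcutaneous fat is
    Background by convention but carries fat HU)."""
    sample = generate_phantom_sample(clean_spec, 5)
    hu, lab = sample.image.values, sample.labels.classes
    outside = ~sample.info["body_mask"]
    assert np.all(hu[outside] <= -900)
    assert np.all(hu[outside] == AIR_HU)
    bg = lab == 0
    lo, hi = clean_spec.muscle_hu_range
    assert not np.any((hu[bg] >= lo) & (hu[bg] <= hi))


def test_fat_and_muscle_hu_disjoint_in_clean_image(clean_spec):
    spec = replace(clean_spec, intramuscular_fat_fraction=0.08)
    sample = generate_phantom_sample(spec, 4)
    hu, lab = sample.image.values, sample.labels.classes
    flo, fhi = spec.fat_hu_range
    muscle_no_pocket = (lab == 1) & ~sample.info["imf_mask"]
    assert not np.any((hu[muscle_no_pocket] >= flo) & (hu[muscle_no_pocket] <= fhi))
    pockets = hu[sample.info["imf_mask"]]
    assert np.all((pockets >= flo) & (pockets <= fhi))


def test_larger_habitus_means_larger_body(small_spec):
    lean = generate_phantom(replace(small_spec, habitus=1.0), 9)[1]
    stout = generate_phantom(replace(small_spec, habitus=1.3), 9)[1]
    assert (stout.classes > 0).sum() > (lean.classes > 0).sum()


@pytest.mark.parametrize("seed", [0, 7, 42])
def test_muscle_ring_encloses_inside(small_spec, seed):
    """4-connected flood fill from the border must not reach any Inside
    pixel without crossing Muscle."""
    _, lab = generate_phantom(small_spec, seed)
    not_muscle = lab.classes != 1
    four = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    comp, _ = ndimage.label(not_muscle, structure=four)
    border_labels = set(comp[0]) | set(comp[-1]) | set(comp[:, 0]) | set(comp[:, -1])
    border_labels.discard(0)
    outside_reach = np.isin(comp, sorted(border_labels))
    assert not np.any(outside_reach & (lab.classes == 2))


def test_intramuscular_pocket_count_matches_fraction(clean_spec):
    spec = replace(clean_spec, intramuscular_fat_fraction=0.1)
    sample = generate_phantom_sample(spec, 2)
    n_muscle = int((sample.labels.classes == 1).sum())
    assert sample.info["imf_count"] == round(0.1 * n_muscle)
    # pockets keep the Muscle label
    assert np.all(sample.labels.classes[sample.info["imf_mask"]] == 1)


@pytest.mark.parametrize(
    "bad, message",
    [
        (dict(image_size=100), "divisible by 32"),
        (dict(fat_hu_range=(-50, 100)), "disjoint"),
        (dict(organ_hu_range=(300, 400)), "intersect"),
        (dict(muscle_hu_range=(150, -29)), "non-empty"),
        (dict(intramuscular_fat_fraction=1.5), "\\[0, 1\\]"),
        (dict(habitus=-1.0), "positive"),
        (dict(noise_sd=-3.0), ">= 0"),
    ],
)
def test_invalid_specs_name_the_violated_invariant(bad, message):
    with pytest.raises(PhantomSpecError, match=message):
        generate_phantom(replace(PhantomSpec(), **bad), 0)


STRATA = {"a": (0.85, 1.0), "b": (1.0, 1.15), "c": (1.15, 1.3)}


def test_cohort_balance_and_determinism(small_spec):
    cohort = generate_cohort(STRATA, 9, 1, base_spec=small_spec)
    counts = {}
    for s in cohort:
        counts[s.info["stratum"]] = counts.get(s.info["stratum"], 0) + 1
    assert counts == {"a": 3, "b": 3, "c": 3}
    again = generate_cohort(STRATA, 9, 1, base_spec=small_spec)
    for x, y in zip(cohort, again):
        assert x.info["stratum"] == y.info["stratum"]
        np.testing.assert_array_equal(x.image.values, y.image.values)


def test_cohort_round_robin_remainder(small_spec):
    cohort = generate_cohort(STRATA, 10, 1, base_spec=small_spec)
    counts = [sum(s.info["stratum"] == k for s in cohort) for k in STRATA]
    assert counts == [4, 3, 3]


def test_cohort_rejects_empty_strata(small_spec):
    with pytest.raises(ValueError, match="stratum"):
        generate_cohort({}, 5, 0, base_spec=small_spec)


def test_stratified_split_contract(small_spec):
    cohort = generate_cohort(STRATA, 30, 2, base_spec=small_spec)
    train, test = stratified_split(cohort, 2, seed=5)
    assert len(test) == 6 and len(train) == 24
    for k in STRATA:
        assert sum(s.info["stratum"] == k for s in test) == 2
    ids = lambda group: {id(s) for s in group}
    assert not (ids(train) & ids(test))
    train2, test2 = stratified_split(cohort, 2, seed=5)
    assert [s.info["index"] for s in test] == [s.info["index"] for s in test2]


def test_stratified_split_requires_training_remainder(small_spec):
    cohort = generate_cohort({"solo": (0.9, 1.1)}, 10, 3, base_spec=small_spec)
    with pytest.raises(ValueError, match="solo"):
        stratified_split(cohort, 10, seed=0)
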