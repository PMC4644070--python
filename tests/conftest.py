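"""Shared fixtures: synthetic datasets and scan helpers."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cdsrna.boxes import GuideKind, GuideRegion, Rejection, annotate_cd_srna
from cdsrna.scan import ScanRules, predict_targets
from cdsrna.synth import SyntheticSpec, generate_dataset

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_guide(sequence: str, kind: GuideKind = GuideKind.D_GUIDE,
               srna_id: str = "g1") -> GuideRegion:
    return GuideRegion(srna_id=srna_id, kind=kind, start=1,
                       end=len(sequence), sequence=sequence)


def annotate_and_predict(dataset, rules: ScanRules = ScanRules()):
    """Run annotate -> predict for every species of a synthetic dataset."""
    results = {}
    for sp in dataset.species:
        srnas = []
        for seq in dataset.srnas[sp]:
            res = annotate_cd_srna(seq)
            assert not isinstance(res, Rejection), (seq.id, res)
            srnas.append(res)
        results[sp] = predict_targets(srnas, dataset.rrnas[sp], rules, species=sp)
    return results


def truth_interaction_set(dataset) -> set[tuple]:
    """(species, sRNA, guide, molecule, site, productive, mode) rows the
    generator's realized truth says a correct pipeline must report."""
    out = set()
    for r in dataset.truth_guides.itertuples():
        if r.expect_significant:
            out.add((r.species, r.srna_id, r.guide_kind, r.molecule,
                     int(r.site), bool(r.expect_productive), r.expect_mode))
    return out


def predicted_interaction_set(results) -> set[tuple]:
    out = set()
    for sp, res in results.items():
        for p in res.predictions:
            out.add((sp, p.srna_id, p.guide_kind.value, p.molecule.value,
                     p.position, p.productive, p.mode.value))
    return out


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def mixed_dataset():
    """Two species with every perturbation class represented."""
    return generate_dataset(
        SyntheticSpec(
            seed=17, n_species=2, n_srnas_per_species=25,
            frac_relaxed_only=0.08, frac_site_mismatch=0.08,
            frac_site_gu=0.04, n_gu_in_duplex=1,
        )
    )


@pytest.fixture(scope="session")
def clean_dataset():
    """All-clean double-guide sRNAs with cross-species shared sites."""
    return generate_dataset(
        SyntheticSpec(
            seed=42, n_species=3, n_srnas_per_species=20,
            frac_decoy=0.0, frac_empty_guide=0.0, frac_site_mismatch=0.0,
            frac_site_gu=0.0, frac_shared_sites=0.25,
        )
    )
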