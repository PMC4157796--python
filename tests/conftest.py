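"""Shared fixtures: a small synthetic study bundle reused across test modules."""

from __future__ import annotations

import pytest

from paumir.simulate import (
    generate_transcriptome,
    plant_cleavage_sites,
    plant_hairpins,
    simulate_degradome,
    simulate_libraries,
)


@pytest.fixture(scope="session")
def small_study():
    """A compact planted study: 20 transcripts, 8 hairpins, 8 cleavage sites."""
    transcripts = generate_transcriptome(20, 800, 0.5, seed=11)
    transcripts, truth = plant_hairpins(transcripts, 8, seed=11)
    transcripts = plant_cleavage_sites(
        transcripts, truth.mature_sequences(), truth, n_sites=8, seed=11
    )
    lib1, lib2 = simulate_libraries(truth, depth=1_000_000, seed=11)
    degradome = simulate_degradome(
        truth, transcripts, peak_height=50, background_rate=0.1, seed=11
    )
    return {
        "transcripts": transcripts,
        "truth": truth,
        "lib1": lib1,
        "lib2": lib2,
        "libs": {lib1.name: lib1, lib2.name: lib2},
        "degradome": degradome,
    }
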