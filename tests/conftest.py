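import numpy as np
import pytest

from crkscreen import synthetic_data as sd

# the documented recovery grid: 3 orientations x 3 separations x 3 sizes
GRID_SEPARATIONS = (4.4, 4.7, 5.0)
GRID_SIZES = (6, 10, 14)


@pytest.fixture(scope="session")
def fixture_grid():
    """All dimer fixture specs of the documented recovery grid."""
    specs = []
    for li, label in enumerate(sd.ORIENTATIONS):
        for si, sep in enumerate(GRID_SEPARATIONS):
            for zi, size in enumerate(GRID_SIZES):
                specs.append(
                    sd.DimerFixtureSpec(
                        orientation_label=label,
                        residues_per_domain=size,
                        interface_separation=sep,
                        planted_contacts=min(5, size),
                        seed=100 * li + 10 * si + zi,
                    )
                )
    return specs


@pytest.fixture(scope="session")
def cohort(tmp_path_factory):
    """A written screening cohort with planted ground truth."""
    out = tmp_path_factory.mktemp("cohort")
    manifest = sd.make_screen_cohort(out, seed=42)
    return out, manifest


def random_alignment(n, L, seed, alphabet="ACGT", gap_rate=0.0, amb_rate=0.0):
    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(n):
        chars = rng.choice(list(alphabet), size=L)
        if gap_rate:
            chars[rng.random(L) < gap_rate] = "-"
        if amb_rate:
            chars[rng.random(L) < amb_rate] = "N"
        rows.append("".join(chars))
    return rows
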