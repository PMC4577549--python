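import numpy as np
import pytest

from lexcast.data_io import MortalitySurface


@pytest.fixture
def toy_hmd_text() -> str:
    return (
        "Mx_1x1 toy table\n"
        "\n"
        "  Year    Age    Female    Male    Total\n"
        "  2000      0    0.005000  0.006000  0.005500\n"
        "  2000      1    0.001000  0.001200  0.001100\n"
        "  2001      0    0.004900  0.005900  0.005400\n"
        "  2001      1    0.000900  0.001100  0.001000\n"
    )


def make_lc_surface(
    n_ages: int = 30,
    n_years: int = 40,
    slope: float = -1.5,
    code: str = "LC",
    first_year: int = 1950,
) -> tuple[MortalitySurface, np.ndarray, np.ndarray, np.ndarray]:
    """Exact rank-1 log-bilinear surface with known (a*, b*, k*)."""
    x = np.arange(n_ages)
    t = np.arange(n_years, dtype=float)
    b = np.exp(-(((x - n_ages / 2) / (n_ages / 3)) ** 2))
    b = b / b.sum()
    k = slope * (t - t.mean())
    a = -6.0 + 0.04 * x
    log_m = a[:, None] + np.outer(b, k)
    surface = MortalitySurface(
        population_code=code,
        sex="total",
        ages=x,
        years=first_year + np.arange(n_years),
        rates=np.exp(log_m),
        open_interval=True,
    )
    return surface, a, b, k


@pytest.fixture
def lc_surface():
    return make_lc_surface()


@pytest.fixture
def flat_surface() -> MortalitySurface:
    """Time-constant surface (degenerate for factor models)."""
    ages = np.arange(20)
    rates = np.tile((0.001 * np.exp(0.08 * ages))[:, None], (1, 12))
    return MortalitySurface(
        population_code="FLAT",
        sex="total",
        ages=ages,
        years=2000 + np.arange(12),
        rates=rates,
    )
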