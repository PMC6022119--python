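"""Generator of apple-like labelled reflectance spectra with session structure.

Real visible-range reflectance spectra of fruit are smooth, broadly two-lobed
curves with class-dependent absorption dips (pigments such as chlorophyll A
absorb near 662 nm).  The generator models a scan as

    intensity(λ) = gain · [ baseline(λ) − Σ bands(λ; class, organic) ]
                   + ambient_offset(λ) + ε,    ε ~ N(0, noise_sd²)

where ``baseline`` is a shared smooth two-lobe curve, each class subtracts
its own set of Gaussian absorption bands (with an amplitude delta when the
specimen is organic), and each acquisition session applies a multiplicative
gain and a low-order-polynomial additive ambient-light offset.  A small
per-specimen amplitude jitter is shared across all scans of one apple, so
specimens — not scans — are the independent units.

The default design mirrors a balanced three-variety study: 44 specimens per
variety, half organic, 4 sampling positions per specimen, 3 scans per
position, two sessions with different ambient conditions.  All randomness
flows from one seed through named substreams.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .rgb import CameraProfile
from .spectra import SampleMeta, SpectraSet, WavelengthGrid

__all__ = [
    "ClassSignature",
    "SessionEffect",
    "SimConfig",
    "DesignFixture",
    "generate_dataset",
    "generate_metameric_dataset",
    "single_band_config",
    "paper_design",
    "price_premium",
]


def _gauss(wl: np.ndarray, centre: float, width: float) -> np.ndarray:
    return np.exp(-(((wl - centre) / width) ** 2))


@dataclass(frozen=True)
class ClassSignature:
    """Absorption bands of one variety: (centre nm, width nm, amplitude) triples.

    ``organic_shift`` gives a per-band amplitude delta added when the
    specimen is organic; it must match ``bands`` in length.
    """

    type_label: str
    bands: tuple[tuple[float, float, float], ...]
    organic_shift: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.organic_shift and len(self.organic_shift) != len(self.bands):
            raise ValueError("organic_shift must have one delta per band")
        for centre, width, _amp in self.bands:
            if width <= 0:
                raise ValueError(f"band width must be positive, got {width}")

    def absorption(self, wl: np.ndarray, organic: bool, jitter: float = 1.0) -> np.ndarray:
        shift = self.organic_shift or (0.0,) * len(self.bands)
        total = np.zeros_like(wl)
        for (centre, width, amp), delta in zip(self.bands, shift):
            a = amp + (delta if organic else 0.0)
            total += jitter * a * _gauss(wl, centre, width)
        return total


@dataclass(frozen=True)
class SessionEffect:
    """Ambient conditions of one acquisition session.

    ``additive_offset`` are polynomial coefficients (constant first) in the
    normalised wavelength u = (λ − λ_min)/(λ_max − λ_min) ∈ [0, 1].
    """

    session_id: str
    additive_offset: tuple[float, ...] = (0.0,)
    gain: float = 1.0
    seed_offset: int = 0

    def __post_init__(self) -> None:
        if self.gain <= 0:
            raise ValueError("gain must be positive")

    def offset(self, wl: np.ndarray) -> np.ndarray:
        u = (wl - wl[0]) / (wl[-1] - wl[0]) if wl.size > 1 else np.zeros_like(wl)
        return sum(c * u**k for k, c in enumerate(self.additive_offset))


def _default_baseline(wl: np.ndarray) -> np.ndarray:
    # broad two-lobe reflectance shape typical of light-skinned fruit
    return 0.45 * _gauss(wl, 470.0, 55.0) + 1.0 * _gauss(wl, 625.0, 75.0) + 0.05


def _default_signatures() -> tuple[ClassSignature, ...]:
    # chlorophyll-like dip at 662 nm in all varieties with differing depth,
    # plus one variety-specific band; organic status shifts the 662 nm depth
    return (
        ClassSignature("Gala", ((662.0, 12.0, 0.20), (550.0, 30.0, 0.10)), (0.03, 0.0)),
        ClassSignature("Braeburn", ((662.0, 12.0, 0.28), (510.0, 25.0, 0.12)), (0.03, 0.01)),
        ClassSignature("PinkLady", ((662.0, 12.0, 0.12), (600.0, 20.0, 0.15)), (0.03, 0.0)),
    )


def _default_sessions() -> tuple[SessionEffect, ...]:
    return (
        SessionEffect("session1"),
        SessionEffect("session2", additive_offset=(0.04, 0.03, -0.02), gain=1.15, seed_offset=1),
    )


@dataclass(frozen=True)
class SimConfig:
    """Study design and noise model; the defaults reproduce a balanced
    three-variety, two-session design (44 specimens per variety, half
    organic, 4 positions × 3 scans each)."""

    grid: WavelengthGrid = field(default_factory=WavelengthGrid.linspace)
    n_per_type: int = 44
    organic_fraction: float = 0.5
    positions_per_specimen: int = 4
    scans_per_position: int = 3
    noise_sd: float = 0.02
    specimen_jitter_sd: float = 0.05
    signatures: tuple[ClassSignature, ...] = field(default_factory=_default_signatures)
    sessions: tuple[SessionEffect, ...] = field(default_factory=_default_sessions)
    baseline: Callable[[np.ndarray], np.ndarray] = _default_baseline
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 0 <= self.organic_fraction <= 1:
            raise ValueError("organic_fraction must be in [0, 1]")
        wl = self.grid.wavelengths
        for sig in self.signatures:
            for centre, _w, _a in sig.bands:
                if not wl[0] <= centre <= wl[-1]:
                    raise ValueError(
                        f"band centre {centre} nm outside grid range "
                        f"[{wl[0]:g}, {wl[-1]:g}]"
                    )


def _country_for(type_label: str, index: int, n_per_type: int) -> str | None:
    """Assign countries following the study design when the count matches it."""
    if n_per_type != 44:
        return None
    table = {
        "Gala": (("Austria", 20), ("U.K.", 24)),
        "Braeburn": (("France", 24), ("Germany", 20)),
        "PinkLady": (("France", 24), ("Italy", 20)),
    }
    if type_label not in table:
        return None
    cum = 0
    for country, count in table[type_label]:
        cum += count
        if index < cum:
            return country
    return None


def generate_dataset(cfg: SimConfig = SimConfig()) -> list[SpectraSet]:
    """Generate one raw-scan :class:`SpectraSet` per configured session.

    Fully determined by ``cfg.seed``: specimen jitter is drawn from a
    specimen substream (shared across sessions, as the same apples are
    re-scanned), scan noise from per-session substreams.
    """
    wl = cfg.grid.wavelengths
    base = cfg.baseline(wl)
    n_org = round(cfg.n_per_type * cfg.organic_fraction)

    specimens: list[tuple[str, ClassSignature, bool, str | None]] = []
    for sig in cfg.signatures:
        for i in range(cfg.n_per_type):
            sid = f"{sig.type_label}-{i + 1:03d}"
            specimens.append((sid, sig, i < n_org, _country_for(sig.type_label, i, cfg.n_per_type)))

    rng_spec = np.random.default_rng([cfg.seed, 101])
    jitter = 1.0 + cfg.specimen_jitter_sd * rng_spec.standard_normal(len(specimens))

    rows_per_session = len(specimens) * cfg.positions_per_specimen * cfg.scans_per_position
    out: list[SpectraSet] = []
    for s_idx, sess in enumerate(cfg.sessions):
        rng_noise = np.random.default_rng([cfg.seed, 202, s_idx + sess.seed_offset])
        offset = sess.offset(wl)
        matrix = np.empty((rows_per_session, wl.size))
        metas: list[SampleMeta] = []
        r = 0
        for k, (sid, sig, organic, country) in enumerate(specimens):
            clean = sess.gain * (base - sig.absorption(wl, organic, jitter[k])) + offset
            for pos in range(1, cfg.positions_per_specimen + 1):
                for scan in range(1, cfg.scans_per_position + 1):
                    matrix[r] = clean + cfg.noise_sd * rng_noise.standard_normal(wl.size)
                    metas.append(
                        SampleMeta(
                            specimen_id=sid,
                            type_label=sig.type_label,
                            organic=organic,
                            session_id=sess.session_id,
                            position_index=pos,
                            scan_index=scan,
                            country=country,
                        )
                    )
                    r += 1
        out.append(SpectraSet(cfg.grid, matrix, metas))
    return out


def single_band_config(
    centre: float = 620.0,
    amplitude: float = 0.15,
    noise_sd: float = 0.02,
    n_per_type: int = 12,
    grid: WavelengthGrid | None = None,
    seed: int = 0,
    **kwargs,
) -> SimConfig:
    """Two-class config whose sole discriminating feature is one Gaussian band.

    Class "banded" subtracts a band of the given amplitude at ``centre``;
    class "plain" has no bands.  Used to test that model inspection recovers
    the informative wavelength.
    """
    return SimConfig(
        grid=grid or WavelengthGrid.linspace(),
        n_per_type=n_per_type,
        noise_sd=noise_sd,
        signatures=(
            ClassSignature("banded", ((centre, 10.0, amplitude),)),
            ClassSignature("plain", ()),
        ),
        sessions=(SessionEffect("session1"),),
        seed=seed,
        **kwargs,
    )


def generate_metameric_dataset(
    cam: CameraProfile,
    grid: WavelengthGrid | None = None,
    n_per_class: int = 60,
    difference_scale: float = 0.25,
    noise_sd: float = 0.02,
    seed: int = 0,
) -> tuple[SpectraSet, np.ndarray]:
    """Two classes whose difference lies in the camera's metameric null space.

    A Gaussian band difference is projected onto the orthogonal complement of
    the camera's three sensitivity rows (resampled to ``grid``), rescaled so
    its largest element is ``difference_scale``, and added to the baseline
    for class "meta_a" only.  By construction the two classes have identical
    noise-free RGB responses under ``cam`` while remaining separable in the
    full spectrum.  Returns the raw set and the projected difference vector.
    """
    grid = grid or WavelengthGrid.linspace()
    wl = grid.wavelengths
    S = cam.sensitivity_matrix(grid)  # 3×p
    d = _gauss(wl, 550.0, 25.0) - 0.5 * _gauss(wl, 620.0, 25.0)
    d_perp = d - S.T @ np.linalg.solve(S @ S.T, S @ d)
    peak = np.max(np.abs(d_perp))
    if peak == 0:
        raise ValueError("difference vector lies entirely in the camera's row space")
    d_perp *= difference_scale / peak

    base = _default_baseline(wl)
    rng = np.random.default_rng([seed, 303])
    matrix = np.empty((2 * n_per_class, wl.size))
    metas: list[SampleMeta] = []
    for i in range(2 * n_per_class):
        label = "meta_a" if i < n_per_class else "meta_b"
        clean = base + (d_perp if label == "meta_a" else 0.0)
        matrix[i] = clean + noise_sd * rng.standard_normal(wl.size)
        metas.append(
            SampleMeta(
                specimen_id=f"{label}-{i:03d}",
                type_label=label,
                organic=False,
                session_id="session1",
                position_index=1,
                scan_index=1,
            )
        )
    return SpectraSet(grid, matrix, metas), d_perp


# ---------------------------------------------------------------------------
# Study-design fixture: specimen counts, countries of origin, shelf prices.


@dataclass(frozen=True)
class DesignFixture:
    """The study's design tables: class counts, origin countries, prices per kg."""

    class_counts: dict[str, int]
    country_table: dict[str, dict[str, int]]
    price_table: dict[tuple[str, bool], float]  # (type, organic) → £/kg

    def __post_init__(self) -> None:
        if sum(self.class_counts.values()) != 132:
            raise ValueError("specimen counts must sum to 132")
        if any(p <= 0 for p in self.price_table.values()):
            raise ValueError("prices must be positive")


def paper_design() -> DesignFixture:
    """The balanced 3 × 44 apple design with its origin and price tables."""
    return DesignFixture(
        class_counts={"Gala": 44, "Braeburn": 44, "PinkLady": 44},
        country_table={
            "Gala": {"Austria": 20, "U.K.": 24},
            "Braeburn": {"France": 24, "Germany": 20},
            "PinkLady": {"France": 24, "Italy": 20},
        },
        price_table={
            ("Gala", False): 2.20,
            ("Gala", True): 3.18,
            ("Braeburn", False): 2.20,
            ("Braeburn", True): 3.18,
            ("PinkLady", False): 3.65,
            ("PinkLady", True): 5.12,
        },
    )


GroupSelector = Callable[[str, bool], bool] | str


def _select_prices(f: DesignFixture, sel: GroupSelector) -> list[float]:
    if callable(sel):
        return [p for (t, o), p in f.price_table.items() if sel(t, o)]
    if sel == "organic":
        return [p for (_t, o), p in f.price_table.items() if o]
    if sel == "non-organic":
        return [p for (_t, o), p in f.price_table.items() if not o]
    return [p for (t, _o), p in f.price_table.items() if t == sel]


def price_premium(f: DesignFixture, group_a: GroupSelector, group_b: GroupSelector) -> float:
    """Mean-price premium of group A over group B, in percent."""
    pa = _select_prices(f, group_a)
    pb = _select_prices(f, group_b)
    if not pa or not pb:
        raise ValueError("empty price group selection")
    return 100.0 * (float(np.mean(pa)) / float(np.mean(pb)) - 1.0)
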