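"""Molecular-clock dating of horizontal-transfer events.

The divergence time in generations between two neutrally evolving copies is
T = K/(2r), with K the substitutions per site and r the per-generation
substitution rate (equal to the mutation rate mu under neutrality).  Because
selective constraint on the compared noncoding regions cannot be excluded,
two bounds are reported: a minimum date T = K/(2*mu) assuming both copies
evolved neutrally, and a maximum date T = K/mu assuming only one did (the
divergence of a single branch).  Generations convert to years through the
mean generations-per-year of the two taxa involved.
"""
from __future__ import annotations

from dataclasses import dataclass

from .distance import count_differences, distance
from .errors import HeltraceError, SaturationError
from .records import SequenceRecord
from .simulate import ClockParams

#: Mandatory caveat attached to every human-readable dating report: the
#: minimum/maximum scheme brackets the date precisely because neutrality of
#: the compared sequences is an assumption, not an observation.
NEUTRALITY_NOTE = (
    "Note: dates assume the compared noncoding regions evolve neutrally; "
    "selective constraint cannot be excluded, which is why a minimum "
    "(both copies neutral) and a maximum (one copy static) date are reported."
)


def avg_gen_per_year(g_a: float, g_b: float) -> float:
    """Arithmetic mean of two generations-per-year estimates."""
    if g_a <= 0 or g_b <= 0:
        raise HeltraceError("generations per year must be positive")
    return 0.5 * (g_a + g_b)


@dataclass
class HTDateEstimate:
    """Dated HT event: K, gen/yr, and min/central/max dates.

    ``T_max_gen`` is exactly twice ``T_min_gen`` (the two clock equations
    differ only by the factor 2) and the central date is the midpoint of the
    bounds, hence 1.5x the minimum.
    """

    K: float
    mu: float
    gen_per_year_avg: float
    T_min_gen: float
    T_max_gen: float
    t_min_mya: float
    t_max_mya: float
    t_central_mya: float
    sites_used: int | None = None

    def report(self) -> str:
        lines = [
            f"K = {self.K:.6g} substitutions/site",
            f"mu = {self.mu:.3g} /site/generation, "
            f"gen/yr = {self.gen_per_year_avg:g}",
            f"T_min = {self.T_min_gen:.6g} generations, "
            f"T_max = {self.T_max_gen:.6g} generations",
            f"date = {self.t_central_mya:.3g} MYA "
            f"({self.t_min_mya:.3g}-{self.t_max_mya:.3g} MYA)",
            NEUTRALITY_NOTE,
        ]
        return "\n".join(lines)


def date_event(K: float, clock: ClockParams) -> HTDateEstimate:
    """Min/max/central date for an event at divergence K.

    T_min = K/(2 mu) and T_max = K/mu generations; calendar dates divide by
    the averaged gen/yr and are reported in MYA.  K = 0 dates to zero.
    """
    if K < 0:
        raise HeltraceError("K must be non-negative")
    clock.validate()
    g = avg_gen_per_year(clock.gen_per_year_a, clock.gen_per_year_b)
    t_min_gen = K / (2.0 * clock.mu)
    t_max_gen = K / clock.mu
    t_min = t_min_gen / g / 1e6
    t_max = t_max_gen / g / 1e6
    return HTDateEstimate(
        K=K,
        mu=clock.mu,
        gen_per_year_avg=g,
        T_min_gen=t_min_gen,
        T_max_gen=t_max_gen,
        t_min_mya=t_min,
        t_max_mya=t_max,
        t_central_mya=0.5 * (t_min + t_max),
    )


def date_from_alignment(
    a: SequenceRecord,
    b: SequenceRecord,
    model: str = "K2P",
    clock: ClockParams | None = None,
) -> HTDateEstimate:
    """Estimate K from a pre-aligned pair, then date the event."""
    clock = clock or ClockParams()
    res = distance(count_differences(a, b), model)
    if res.saturated:
        raise SaturationError(
            f"distance between {a.id!r} and {b.id!r} is saturated under "
            f"{model}; the pair is undatable"
        )
    est = date_event(res.K, clock)
    est.sites_used = res.sites_used
    return est
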