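"""Normal priors on the log relative risk, elicited from tail constraints.

Three priors are used for the mortality reanalysis:

* ``non_informative`` - N(0, 10^2): effectively flat over plausible log RRs.
* ``pessimistic`` - mean ln(1.1) (a clinically meaningful 10% excess risk),
  with the SD chosen so the prior puts 5% mass on "no effect" (RR <= 1).
* ``skeptical`` - mean 0 (no effect), with the SD chosen so the prior puts
  5% mass on RR > 1.1.

An optimistic prior (mortality lower in nonagenarians) is deliberately not
provided: lower mortality in the older group was considered clinically
implausible.  Both tail constraints elicit the same SD, ln(1.1)/z(0.95)
~= 0.058.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.stats import norm

VALID_LABELS = ("non_informative", "pessimistic", "skeptical", "custom")


@dataclass(frozen=True)
class PriorSpec:
    """A normal prior on the log relative risk."""

    label: str
    mean_log_rr: float
    sd_log_rr: float
    constraint_note: str = ""

    def __post_init__(self):
        if self.sd_log_rr <= 0:
            raise ValueError("sd_log_rr must be > 0")
        if self.label not in VALID_LABELS:
            raise ValueError(f"label must be one of {VALID_LABELS}")


def elicit_sd_from_tail(
    mean_rr: float, threshold_rr: float, tail_prob: float
) -> float:
    """SD (log scale) putting exactly ``tail_prob`` mass beyond ``threshold_rr``.

    For a normal prior centred at ln(mean_rr), the unique SD with
    ``tail_prob`` mass on the far side of ln(threshold_rr) is
    |ln(threshold_rr) - ln(mean_rr)| / z(1 - tail_prob).
    """
    if mean_rr <= 0 or threshold_rr <= 0:
        raise ValueError("ratios must be positive")
    if math.isclose(mean_rr, threshold_rr):
        raise ValueError("mean at threshold: no finite SD satisfies the constraint")
    if not 0 < tail_prob < 0.5:
        raise ValueError("tail_prob must lie in (0, 0.5)")
    z = norm.ppf(1.0 - tail_prob)
    return abs(math.log(threshold_rr) - math.log(mean_rr)) / z


def standard_priors() -> dict[str, PriorSpec]:
    """The three study priors, keyed by label."""
    sd = elicit_sd_from_tail(mean_rr=1.1, threshold_rr=1.0, tail_prob=0.05)
    return {
        "non_informative": PriorSpec(
            "non_informative", 0.0, 10.0, "mean 0, SD 10 on the log scale"
        ),
        "pessimistic": PriorSpec(
            "pessimistic",
            math.log(1.1),
            sd,
            "mean ln(1.1); 5% prior mass on no effect (RR <= 1)",
        ),
        "skeptical": PriorSpec(
            "skeptical",
            0.0,
            elicit_sd_from_tail(mean_rr=1.0, threshold_rr=1.1, tail_prob=0.05),
            "mean 0; 5% prior mass on RR > 1.1",
        ),
    }


def prior_tail_prob(prior: PriorSpec, threshold_rr: float, side: str) -> float:
    """Prior mass above/below ``threshold_rr`` under the normal log-RR prior."""
    if side not in ("above", "below"):
        raise ValueError("side must be 'above' or 'below'")
    z = (math.log(threshold_rr) - prior.mean_log_rr) / prior.sd_log_rr
    upper = float(norm.sf(z))
    return upper if side == "above" else 1.0 - upper
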