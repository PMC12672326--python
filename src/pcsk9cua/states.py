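"""Health-state space of the cardiovascular Markov cohort model.

Eleven mutually exclusive states track first and recurrent myocardial
infarction (MI) and ischemic stroke (IS), with one-cycle tunnel states for
the first post-event year and two absorbing death states. Revascularization
is handled as a cost/disutility overlay, not a state.
"""

from __future__ import annotations

from enum import IntEnum


class HealthState(IntEnum):
    """Model states, in the fixed index order used by all matrices/traces."""

    NO_CVD = 0
    MI_Y1 = 1          # first MI, year 1 (tunnel)
    POST_MI = 2
    MI2_Y1 = 3         # second-or-later MI, year 1 (tunnel)
    POST_MI2 = 4
    IS_Y1 = 5          # first IS, year 1 (tunnel)
    POST_IS = 6
    IS2_Y1 = 7         # second-or-later IS, year 1 (tunnel)
    POST_IS2 = 8
    CV_DEATH = 9
    NON_CV_DEATH = 10


N_STATES = len(HealthState)

ABSORBING = (HealthState.CV_DEATH, HealthState.NON_CV_DEATH)
ALIVE = tuple(s for s in HealthState if s not in ABSORBING)
TUNNELS = (HealthState.MI_Y1, HealthState.MI2_Y1,
           HealthState.IS_Y1, HealthState.IS2_Y1)

#: tunnel state -> the post-event state it drains into after one cycle
TUNNEL_EXIT = {
    HealthState.MI_Y1: HealthState.POST_MI,
    HealthState.MI2_Y1: HealthState.POST_MI2,
    HealthState.IS_Y1: HealthState.POST_IS,
    HealthState.IS2_Y1: HealthState.POST_IS2,
}

MI_PATHWAY = (HealthState.MI_Y1, HealthState.POST_MI,
              HealthState.MI2_Y1, HealthState.POST_MI2)
IS_PATHWAY = (HealthState.IS_Y1, HealthState.POST_IS,
              HealthState.IS2_Y1, HealthState.POST_IS2)
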