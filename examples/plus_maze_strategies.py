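"""Place versus response strategies on the plus maze.

Agents are trained from the south arm to a west-arm reward; probe trials
start from the (previously blocked) north arm.  Reaching the trained
allocentric goal arm counts as a place strategy; repeating the trained
egocentric turn (ending in the east arm) counts as a response strategy.
Each probe is also re-run after devaluing the reinforcer (the hippocampal
reward representation is scaled to zero; striatal weights are untouched).
"""

from dualsys import run_plus_maze

for arm in ("control", "hpc", "dls"):
    res = run_plus_maze(n_agents=20, arm=arm, seed=0)
    print(f"arm = {arm}")
    for p, d in zip(res.proportions, res.deval_proportions):
        print(
            f"  probe day {p['day']:2d}: place {p['place']:.2f}"
            f"  response {p['response']:.2f} | devalued: response {d['response']:.2f}"
        )
# Controls start with a place strategy and switch to response with extended
# training; striatal (dls) inactivation prevents the switch, hippocampal
# (hpc) inactivation forces early response behavior, and devaluation flips
# controls (but not hpc-lesioned agents, already responders) to response.
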