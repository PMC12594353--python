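"""Independent step-by-step likelihood oracle used by the test suite.

Deliberately written from the model equations in the most literal style
possible (dict state, explicit per-model branches, plain ``math``), with no
imports from the package, so that agreement with the package's vectorized /
compiled likelihood is a genuine two-route check.
"""

import math


def oracle_choice_prob_option1(model_id, params, v1, v2):
    beta = params["beta"]
    if model_id == "FU_RP_IP":
        return 1.0 / (1.0 + math.exp(beta * (params["alpha"] - (v1 - v2))))
    return 1.0 / (1.0 + math.exp(beta * (v2 - v1)))


def oracle_choice_prob(model_id, params, v1, v2, choice):
    """Probability of the observed choice, evaluated directly (never as
    1 - p(other), which cancels catastrophically for near-certain choices)."""
    beta = params["beta"]
    alpha = params["alpha"] if model_id == "FU_RP_IP" else 0.0
    d = v1 - v2
    if choice == 1:
        return 1.0 / (1.0 + math.exp(beta * (alpha - d)))
    return 1.0 / (1.0 + math.exp(beta * (d - alpha)))


def oracle_update(model_id, params, V, n, choice, outcome,
                  fictitious_pe="unchosen", rate_select="factual"):
    """Mutate value dict V (and EWA weight dict n) for one learning step."""
    other = 2 if choice == 1 else 1
    if model_id == "RW":
        V[choice] = V[choice] + params["eta"] * (outcome - V[choice])
    elif model_id == "RP":
        if outcome > 0:
            V[choice] = V[choice] + params["eta_pos"] * (outcome - V[choice])
        else:
            V[choice] = V[choice] + params["eta_neg"] * (outcome - V[choice])
    elif model_id == "EWA":
        n_prev = n[choice]
        n[choice] = n[choice] * params["rho"] + 1.0
        V[choice] = (V[choice] * params["phi"] * n_prev + outcome) / n[choice]
    elif model_id == "FU":
        v_chosen_before = V[choice]
        V[choice] = V[choice] + params["eta"] * (outcome - V[choice])
        if fictitious_pe == "chosen":
            V[other] = V[other] + params["eta"] * (-outcome - v_chosen_before)
        else:
            V[other] = V[other] + params["eta"] * (-outcome - V[other])
    elif model_id in ("FU_RP", "FU_RP_IP"):
        if outcome > 0:
            rate_c = params["eta_pos"]
        else:
            rate_c = params["eta_neg"]
        if rate_select == "per-option":
            rate_o = params["eta_pos"] if -outcome > 0 else params["eta_neg"]
        else:
            rate_o = rate_c
        v_chosen_before = V[choice]
        V[choice] = V[choice] + rate_c * (outcome - V[choice])
        if fictitious_pe == "chosen":
            V[other] = V[other] + rate_o * (-outcome - v_chosen_before)
        else:
            V[other] = V[other] + rate_o * (-outcome - V[other])
    else:
        raise ValueError(model_id)


def oracle_loglik(model_id, params, choices, outcomes,
                  fictitious_pe="unchosen", rate_select="factual"):
    """Summed log-likelihood plus the per-trial vector, straight from the
    equations; missing responses (choice 0) are skipped entirely."""
    V = {1: 0.0, 2: 0.0}
    n = {1: 1.0, 2: 1.0}
    total = 0.0
    per_trial = []
    for choice, outcome in zip(choices, outcomes):
        if choice == 0:
            per_trial.append(0.0)
            continue
        p = oracle_choice_prob(model_id, params, V[1], V[2], int(choice))
        lp = math.log(p)
        total += lp
        per_trial.append(lp)
        oracle_update(model_id, params, V, n, int(choice), int(outcome),
                      fictitious_pe=fictitious_pe, rate_select=rate_select)
    return total, per_trial


def random_params(model_id, rng):
    """A parameter draw well inside the bounds (away from softmax saturation)."""
    draw = {
        "eta": rng.uniform(0.05, 0.95),
        "eta_pos": rng.uniform(0.05, 0.95),
        "eta_neg": rng.uniform(0.05, 0.95),
        "phi": rng.uniform(0.05, 0.95),
        "rho": rng.uniform(0.05, 0.95),
        "beta": rng.uniform(0.1, 8.0),
        "alpha": rng.uniform(-1.0, 1.0),
    }
    names = {
        "RW": ("eta", "beta"),
        "RP": ("eta_pos", "eta_neg", "beta"),
        "EWA": ("phi", "rho", "beta"),
        "FU": ("eta", "beta"),
        "FU_RP": ("eta_pos", "eta_neg", "beta"),
        "FU_RP_IP": ("eta_pos", "eta_neg", "beta", "alpha"),
    }[model_id]
    return {k: draw[k] for k in names}
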