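import numpy as np
import pytest

from elicitbn import Family, FamilyParams, NodeDescriptor, quantile
from elicitbn.elicitation import ProbabilityAssessment

#: one representative parameter set per family, used across tests
FAMILY_EXAMPLES = {
    Family.NORMAL: FamilyParams(Family.NORMAL, {"loc": 3.0, "scale": 2.0}),
    Family.STUDENT_T: FamilyParams(Family.STUDENT_T,
                                   {"loc": 1.0, "scale": 0.5, "df": 3.0}),
    Family.SHIFTED_GAMMA: FamilyParams(Family.SHIFTED_GAMMA,
                                       {"shape": 2.5, "rate": 0.5},
                                       support_lower=1.0),
    Family.MIRROR_GAMMA: FamilyParams(Family.MIRROR_GAMMA,
                                      {"shape": 2.5, "rate": 0.5},
                                      support_upper=20.0),
    Family.LOGNORMAL: FamilyParams(Family.LOGNORMAL,
                                   {"mu": 1.0, "sigma": 0.4},
                                   support_lower=0.0),
    Family.LOG_T: FamilyParams(Family.LOG_T,
                               {"mu": 1.0, "sigma": 0.3, "df": 3.0},
                               support_lower=0.0),
    Family.MIRROR_LOG_T: FamilyParams(Family.MIRROR_LOG_T,
                                      {"mu": 1.0, "sigma": 0.3, "df": 3.0},
                                      support_upper=10.0),
    Family.SHIFTED_SCALED_BETA: FamilyParams(Family.SHIFTED_SCALED_BETA,
                                             {"alpha": 2.0, "beta": 5.0},
                                             support_lower=0.0,
                                             support_upper=1.0),
}

STANDARD_PROBS = (0.01, 0.25, 0.5, 0.75, 0.99)


def assessment_from(params: FamilyParams,
                    probs=STANDARD_PROBS,
                    expert_id: str = "E1",
                    node_id: str = "x",
                    support=None) -> ProbabilityAssessment:
    """Exact quantiles of a known distribution, packaged as an assessment."""
    q = np.asarray(quantile(params, np.asarray(probs)))
    if support is None:
        support = params.support
    return ProbabilityAssessment(expert_id, node_id,
                                 tuple(zip(probs, map(float, q))),
                                 support=support)


@pytest.fixture
def proportion_node():
    return NodeDescriptor("prop", "proportion")


@pytest.fixture
def continuous_node():
    return NodeDescriptor("marker", "continuous", units="UI/mL",
                          support=(0.0, float("inf")))
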