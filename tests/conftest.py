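import numpy as np
import pandas as pd
import pytest

from glycoproteomap import builtin_catalog, load_annotations
from glycoproteomap.nomenclature import matches
from glycoproteomap.traits import PEAK_IDS


@pytest.fixture(scope="session")
def annotations():
    return load_annotations()


@pytest.fixture(scope="session")
def catalog():
    return builtin_catalog()


def random_profiles(n, rng):
    """Random compositions over the 36 peaks, in percent."""
    return pd.DataFrame(rng.dirichlet(np.ones(len(PEAK_IDS)), size=n) * 100.0,
                        columns=list(PEAK_IDS))


def brute_force_trait(defn, profile, annotations, catalog, policy="dominant"):
    """Re-derive one trait value by explicit peak enumeration.

    Independent of the catalog engine: walks every peak, re-tests the
    structural predicates via ``matches`` and accumulates plain Python
    floats.  Ratio traits recurse on their components.
    """
    def peak_set(selector):
        if isinstance(selector, tuple):
            return list(selector)
        hits = []
        for pid, ann in annotations.items():
            structs = [ann.dominant] if policy == "dominant" else list(ann.structures)
            if any(matches(s, selector) for s in structs):
                hits.append(pid)
        return hits

    if defn.kind == "ratio":
        num = brute_force_trait(catalog[defn.numerator_trait], profile, annotations,
                                catalog, policy)
        den = brute_force_trait(catalog[defn.denominator_trait], profile, annotations,
                                catalog, policy)
        return num / den if den == den and den != 0 else float("nan")

    num = sum(profile[p] for p in peak_set(defn.numerator))
    if defn.kind in ("primary", "group_percent"):
        return float(num)
    den_peaks = list(annotations) if defn.denominator == "total" \
        else peak_set(defn.denominator)
    den = sum(profile[p] for p in den_peaks)
    if den != den or den == 0:
        return float("nan")
    return 100.0 * num / den
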