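"""Family-level evidence: segregation, de novo detection, phase, markers.

Builds a trio in which the affected child carries two heterozygous
variants in a recessive gene — one inherited from the mother, one absent
from both parents — and checks segregation, parental origin and the
marker-based Mendelian consistency that turns an apparent de novo event
into a confirmed one.
"""

import numpy as np

from rptriage.segregation import (
    check_segregation,
    check_trans_phase,
    detect_de_novo,
    mendelian_consistency,
)
from rptriage.types import (
    Family,
    Genotype,
    InheritanceMode,
    MarkerGenotype,
    PedigreeMember,
    VariantLocus,
)

M1 = VariantLocus("chr1", 2276, "G", "T")   # maternally inherited
M2 = VariantLocus("chr1", 5576, "T", "G")   # de novo

family = Family("F1")
family.add(PedigreeMember("DAD", "F1", "male", False))
family.add(PedigreeMember("MOM", "F1", "female", False))
family.add(PedigreeMember("KID", "F1", "female", True, father_id="DAD", mother_id="MOM"))
family.members["KID"].genotypes = {M1: Genotype.HET, M2: Genotype.HET}
family.members["MOM"].genotypes = {M1: Genotype.HET, M2: Genotype.REF_REF}
family.members["DAD"].genotypes = {M1: Genotype.REF_REF, M2: Genotype.REF_REF}

verdict = check_segregation([M1, M2], family, "KID", InheritanceMode.AR)
print(f"segregation under AR: {verdict.status.value}")
print(f"de novo loci:         {[str(l) for l in verdict.de_novo_loci]}")
print(f"M2 de novo test:      {detect_de_novo(Genotype.HET, Genotype.REF_REF, Genotype.REF_REF)}")
print(f"phase of M1/M2:       {check_trans_phase(family, 'KID', M1, M2)}")

# sixteen polymorphic markers, child drawing one allele from each parent
rng = np.random.default_rng(0)
pool = [f"a{i}" for i in range(8)]
father_mk, mother_mk, child_mk = [], [], []
for k in range(16):
    fa = [pool[rng.integers(8)] for _ in range(2)]
    mo = [pool[rng.integers(8)] for _ in range(2)]
    father_mk.append(MarkerGenotype(f"MK{k:02d}", *fa))
    mother_mk.append(MarkerGenotype(f"MK{k:02d}", *mo))
    child_mk.append(MarkerGenotype(f"MK{k:02d}", fa[0], mo[1]))

consistent, total, confirmed = mendelian_consistency(child_mk, father_mk, mother_mk)
print(f"markers consistent:   {consistent}/{total} -> paternity confirmed: {confirmed}")

print(
    "\nBoth alleles track with disease (unaffected parents each carry at\n"
    "most one), the pair is in trans (maternal + de novo), and the fully\n"
    "consistent marker set confirms the de novo event rather than a\n"
    "sample mix-up or non-paternity."
)
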