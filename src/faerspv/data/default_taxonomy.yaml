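# Default reaction-term taxonomy (editable; exact-string, case-insensitive).
#
# reaction_categories assign each Preferred Term to one category; the first
# category listing the term wins.  Unlisted terms are "other".
#
# exposure_context drives case selection: in_utero terms are positive evidence
# of prenatal exposure; exclusions are checked in the listed order and the
# first match wins.  A category with rescued_by_in_utero true does NOT exclude
# a report that also carries an in-utero term (abuse/dependence "without
# mention of in utero exposure").

reaction_categories:
  eye_disorder_general:
    - strabismus
    - amblyopia
    - miosis
    - nystagmus
    - visual impairment
    - visual acuity reduced
    - refraction disorder
    - blindness
    - eye movement disorder
    - blepharospasm
    - conjunctivitis neonatal
    - hypermetropia
    - astigmatism
    - myopia
  eye_disorder_congenital:
    - optic nerve hypoplasia
    - congenital nystagmus
    - microphthalmia
    - anophthalmos
    - coloboma
    - cataract congenital
    - optic atrophy congenital
    - congenital eye disorder
  withdrawal_neonatal:
    - drug withdrawal syndrome neonatal
    - neonatal abstinence syndrome
  exposure_context:
    - foetal exposure during pregnancy
    - fetal exposure during pregnancy
    - maternal exposure during pregnancy
    - exposure during pregnancy
    - maternal exposure timing unspecified
    - drug abuse
    - drug dependence
    - substance abuse
    - accidental exposure to product
    - accidental poisoning
    - accidental overdose
    - toxicity to various agents
    - poisoning
    - overdose
    - suicide attempt
    - completed suicide
    - intentional self-injury
    - substance use disorder
    - anaesthetic complication
    - exposure during anaesthesia
    - product use for unknown indication
    - drug use for unknown indication

exposure_context:
  in_utero:
    - foetal exposure during pregnancy
    - fetal exposure during pregnancy
    - maternal exposure during pregnancy
    - exposure during pregnancy
    - maternal exposure timing unspecified
    - drug withdrawal syndrome neonatal
    - neonatal abstinence syndrome
  exclusions:
    - category: abuse_dependence
      rescued_by_in_utero: true
      patterns:
        - drug abuse
        - drug dependence
        - substance abuse
    - category: accidental_exposure
      rescued_by_in_utero: false
      patterns:
        - accidental exposure to product
        - accidental poisoning
        - accidental overdose
    - category: toxicity_poisoning_overdose
      rescued_by_in_utero: false
      patterns:
        - toxicity to various agents
        - poisoning
        - overdose
    - category: suicide
      rescued_by_in_utero: false
      patterns:
        - suicide attempt
        - completed suicide
        - intentional self-injury
    - category: substance_use_disorder
      rescued_by_in_utero: false
      patterns:
        - substance use disorder
    - category: anaesthesia_related
      rescued_by_in_utero: false
      patterns:
        - anaesthetic complication
        - exposure during anaesthesia
    - category: indication_only
      rescued_by_in_utero: false
      patterns:
        - pain
        - product use for unknown indication
        - drug use for unknown indication
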