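# Two-syllable demonstration score: /ma/ + /li/, both High tone.
# Units are arbitrary for the vocal-tract channels; f0 is in semitones
# relative to 100 Hz.
dimensions:
  - {name: f0, unit: st, tier: T}
  - {name: F2, unit: Hz, tier: V}
  - {name: lip-aperture, unit: arb, tier: C}
  - {name: tongue-tip, unit: arb, tier: C}

syllables:
  - label: ma
    duration: 0.2
    onset:
      - label: m
        role: onset-C
        targets:
          lip-aperture: {slope: 0, height: -5, strength: 50}
        constrained: [lip-aperture]
    nucleus:
      - label: a
        role: nucleus-V
        targets:
          F2: {slope: 0, height: 1100, strength: 30}
          lip-aperture: {slope: 0, height: 5, strength: 30}
          tongue-tip: {slope: 0, height: 0, strength: 30}
    tone:
      label: H
      role: tone-T
      targets:
        f0: {slope: 0, height: 4, strength: 30}

  - label: li
    duration: 0.2
    onset:
      - label: l
        role: onset-C
        targets:
          tongue-tip: {slope: 0, height: -4, strength: 50}
        constrained: [tongue-tip]
    nucleus:
      - label: i
        role: nucleus-V
        targets:
          F2: {slope: 0, height: 2200, strength: 30}
          lip-aperture: {slope: 0, height: 3, strength: 30}
          tongue-tip: {slope: 0, height: 1, strength: 30}
    tone:
      label: H
      role: tone-T
      targets:
        f0: {slope: 0, height: 4, strength: 30}
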