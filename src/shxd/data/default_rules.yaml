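name: shxd-default
version: '1.0'
rules:
  sexual_history:
    match:
    - pattern: sex[a-z,\.,\s,\/]|intercourse
      note: sex followed by letter/space/period/slash, or intercourse
    - pattern: sex\Z
      note: bare 'sex' at end of text
    exclude: []
  protection_used:
    match:
    - pattern: protect
      note: ''
    - pattern: condom
      note: ''
    exclude:
    - pattern: condom cath
      note: condom catheter is a urinary device
    - pattern: child protect
      note: child protective services
  sti_testing:
    match:
    - pattern: GC[^S]
      note: gonorrhea/chlamydia shorthand; [^S] avoids the Glasgow Coma Scale 'GCS'
    - pattern: G\/C
      note: ''
    - pattern: gonorr
      note: ''
    - pattern: gonnor
      note: common misspelling
    - pattern: gonor
      note: ''
    - pattern: gonoc
      note: gonococcal
    - pattern: chlam
      note: ''
    - pattern: ST[ID]\s(test|screen|lab)
      note: ''
    - pattern: test(ing|ed)?\s+for\sST[ID]
      note: ''
    exclude:
    - pattern: chlam pneumo
      note: Chlamydophila pneumoniae is respiratory, not an STI
    - pattern: chlamydia pneumo
      note: ''
  not_sexually_active:
    match:
    - pattern: denies (any sex|history of sex|hx of sex|intercourse|hx of intercourse|being
        sexual|ever being sexual)|no sex|never (had sex|been sexual)|not sexually
        active
      note: ''
    exclude: []
  partner_gender:
    match: []
    exclude: []
    window:
      anchors:
      - pattern: sex[a-z,\.,\s,\/]|intercourse
        note: sex followed by letter/space/period/slash, or intercourse
      - pattern: sex\Z
        note: bare 'sex' at end of text
      chars: 50
      targets:
      - pattern: male
        note: substring also covers 'female'
      - pattern: boy
        note: ''
      - pattern: girl
        note: ''
      - pattern: men
        note: substring also covers 'women'
      - pattern: man
        note: ''
  sexual_practice:
    match:
    - pattern: (oral|vaginal|anal)\s(sex|penetration|intercourse)
      note: ''
    exclude: []
  contraception_used:
    match:
    - pattern: OCP
      note: oral contraceptive pill
    - pattern: contraceptive
      note: ''
    - pattern: contraception
      note: ''
    - pattern: birth control
      note: ''
    - pattern: planon
      note: substring covers Nexplanon/Implanon
    - pattern: IUD
      note: ''
    - pattern: nuvaring
      note: ''
    - pattern: depo
      note: depot medroxyprogesterone
    exclude: []
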