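# SYNTHETIC stand-in domain annotation for the eight-chain TCR-CD3 complex.
#
# The chain layout (TCRalpha/TCRbeta, two CD3-epsilon chains paired with
# CD3gamma and CD3delta, and the CD3zeta homodimer) and the Ig loop/strand
# naming follow the standard convention for immunoglobulin-like domains.
# The residue spans below are NOT taken from the cryo-EM deposition -- they
# are a self-consistent synthetic numbering used by the packaged fixture
# generator.  For analysis of real structures, copy this file and edit the
# spans to match the numbering of your coordinates.
chains:
  A: TCRalpha
  B: TCRbeta
  E: CD3epsilon_g
  G: CD3gamma
  F: CD3epsilon_d
  D: CD3delta
  Z: CD3zeta
  Y: CD3zeta_prime

# The three EC dimers, in the fixed analysis order TCRab < CD3ed < CD3eg.
dimers:
  TCRab: [A, B]
  CD3ed: [F, D]
  CD3eg: [E, G]

domains:
  Valpha:        {chain: A, start: 1,   end: 110}
  Calpha:        {chain: A, start: 118, end: 200}
  Vbeta:         {chain: B, start: 1,   end: 115}
  Cbeta:         {chain: B, start: 120, end: 230}
  CD3epsilon_g:  {chain: E, start: 1,   end: 100}
  CD3gamma:      {chain: G, start: 1,   end: 90}
  CD3epsilon_d:  {chain: F, start: 1,   end: 100}
  CD3delta:      {chain: D, start: 1,   end: 85}
  CD3zeta:       {chain: Z, start: 1,   end: 8}
  CD3zeta_prime: {chain: Y, start: 1,   end: 8}

tm_helices:
  TCRalpha:      {chain: A, start: 255, end: 278}
  TCRbeta:       {chain: B, start: 250, end: 273}
  CD3epsilon_g:  {chain: E, start: 110, end: 133}
  CD3gamma:      {chain: G, start: 100, end: 123}
  CD3epsilon_d:  {chain: F, start: 110, end: 133}
  CD3delta:      {chain: D, start: 95,  end: 118}
  CD3zeta:       {chain: Z, start: 15,  end: 38}
  CD3zeta_prime: {chain: Y, start: 15,  end: 38}

elements:
  "Valpha A'B loop":  {chain: A, start: 15,  end: 20}
  "Valpha C''D loop": {chain: A, start: 65,  end: 70}
  "Valpha EF loop":   {chain: A, start: 80,  end: 85}
  "Calpha AB loop":   {chain: A, start: 130, end: 136}
  "Calpha DE loop":   {chain: A, start: 160, end: 166}
  "Cbeta A strand":   {chain: B, start: 122, end: 127}
  "Cbeta B strand":   {chain: B, start: 132, end: 138}
  "Cbeta CC' loop":   {chain: B, start: 150, end: 156}
  "Cbeta EF loop":    {chain: B, start: 190, end: 196}
  "Cbeta FG loop":    {chain: B, start: 205, end: 214}
  "Cbeta G strand":   {chain: B, start: 218, end: 224}
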