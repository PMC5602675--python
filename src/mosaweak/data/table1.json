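[
  {
    "name": "Mosasauroidea",
    "type": "branch",
    "internal": ["Mosasaurus hoffmannii", "Aigialosaurus dalmaticus"],
    "external": ["Dolichosaurus longicollis", "Adriosaurus suessi", "Pontosaurus lesinensis"],
    "authorship": "new definition"
  },
  {
    "name": "Aigialosauridae",
    "type": "branch",
    "internal": ["Aigialosaurus dalmaticus", "Opetiosaurus bucchichi"],
    "external": [
      "Dolichosaurus longicollis",
      "Adriosaurus suessi",
      "Pontosaurus lesinensis",
      {"node_of": ["Mosasaurus hoffmannii", "Halisaurus platyspondylus", "Tylosaurus proriger"]}
    ],
    "authorship": "new definition"
  },
  {
    "name": "Mosasauridae",
    "type": "node",
    "internal": ["Mosasaurus hoffmannii", "Halisaurus platyspondylus", "Tylosaurus proriger"],
    "external": [],
    "authorship": "earlier definition, followed"
  },
  {
    "name": "Halisaurinae",
    "type": "branch",
    "internal": ["Halisaurus platyspondylus"],
    "external": ["Mosasaurus hoffmannii", "Tylosaurus proriger", "Tethysaurus nopcsai", "Yaguarasaurus columbianus"],
    "authorship": "new definition"
  },
  {
    "name": "Natantia",
    "type": "branch",
    "internal": ["Mosasaurus hoffmannii", "Tylosaurus proriger", "Plioplatecarpus marshii"],
    "external": ["Halisaurus platyspondylus"],
    "authorship": "earlier definition, followed"
  },
  {
    "name": "Mosasaurinae",
    "type": "branch",
    "internal": ["Mosasaurus hoffmannii"],
    "external": ["Tylosaurus proriger", "Plioplatecarpus marshii", "Halisaurus platyspondylus", "Tethysaurus nopcsai", "Yaguarasaurus columbianus"],
    "authorship": "new definition"
  },
  {
    "name": "Mosasaurini",
    "type": "branch",
    "internal": ["Mosasaurus hoffmannii"],
    "external": ["Globidens alabamaensis"],
    "authorship": "new definition"
  },
  {
    "name": "Globidensini",
    "type": "branch",
    "internal": ["Globidens alabamaensis"],
    "external": ["Mosasaurus hoffmannii"],
    "authorship": "new definition"
  },
  {
    "name": "Russellosaurina",
    "type": "node",
    "internal": ["Russellosaurus coheni", "Tylosaurus proriger", "Plioplatecarpus marshii"],
    "external": ["Mosasaurus hoffmannii"],
    "authorship": "new definition"
  },
  {
    "name": "Tethysaurinae",
    "type": "node",
    "internal": ["Tethysaurus nopcsai", "Pannoniasaurus inexpectatus"],
    "external": ["Halisaurus platyspondylus", "Mosasaurus hoffmannii", "Tylosaurus proriger", "Plioplatecarpus marshii", "Yaguarasaurus columbianus"],
    "authorship": "new definition"
  },
  {
    "name": "Yaguarasaurinae",
    "type": "node",
    "internal": ["Yaguarasaurus columbianus", "Russellosaurus coheni", "Romeosaurus fumanensis"],
    "external": ["Tethysaurus nopcsai", "Halisaurus platyspondylus", "Tylosaurus proriger", "Plioplatecarpus marshii", "Mosasaurus hoffmannii"],
    "authorship": "new definition"
  },
  {
    "name": "Plioplatecarpinae",
    "type": "branch",
    "internal": ["Plioplatecarpus marshii"],
    "external": ["Mosasaurus hoffmannii", "Tylosaurus proriger", "Tethysaurus nopcsai", "Yaguarasaurus columbianus"],
    "authorship": "new definition"
  },
  {
    "name": "Tylosaurinae",
    "type": "branch",
    "internal": ["Tylosaurus proriger"],
    "external": ["Plioplatecarpus marshii", "Mosasaurus hoffmannii"],
    "authorship": "earlier definition, followed"
  }
]
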