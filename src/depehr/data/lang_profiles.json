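{
  "comment": "Discriminative function words and word-final character n-grams for Spanish vs Catalan note-language identification. Lists are disjoint between the two profiles.",
  "es": {
    "words": [
      "los", "las", "una", "con", "sin", "como", "pero", "muy", "donde",
      "hoy", "desde", "hasta", "bien", "y", "al", "del", "lo",
      "paciente", "tratamiento", "seguimiento", "pruebas", "acude",
      "refiere", "niega", "presenta", "dentro", "ultima", "última",
      "años", "meses", "derecha", "izquierda", "signos", "síntomas",
      "sintomas", "actualidad", "observa", "persiste", "insomnio",
      "exploración", "exploracion", "evolución", "evolucion", "física",
      "fisica", "analítica", "analitica", "medicación", "medicacion"
    ],
    "suffixes": ["ción", "cion", "dad", "ivo"]
  },
  "ca": {
    "words": [
      "els", "les", "amb", "sense", "com", "però", "molt", "on",
      "avui", "des", "fins", "bé", "i",
      "pacient", "tractament", "seguiment", "proves", "acudeix",
      "refereix", "nega", "dins", "darrera", "anys", "mesos",
      "dreta", "esquerra", "signes", "símptomes", "simptomes",
      "actualitat", "persisteix", "insomni", "exploració", "exploracio",
      "evolució", "evolucio", "medicació", "medicacio",
      "aquest", "aquesta", "també"
    ],
    "suffixes": ["ció", "cio", "tat", "iu"]
  }
}
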