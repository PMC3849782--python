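{
  "description": "Published EST profile counts for the two plant CPP gene groups: per source database and species subset, the numbers of redundant and unique ESTs aligned to Group I and Group II genes and the counts common to both groups.",
  "dbEST": {
    "all": {
      "genes": {"I": 57, "II": 38},
      "redundant": {"I": 516, "II": 294, "common": 165},
      "unique": {"I": 125, "II": 90, "common": 5}
    },
    "arabidopsis": {
      "genes": {"I": 8, "II": 6},
      "redundant": {"I": 48, "II": 26, "common": 8},
      "unique": {"I": 20, "II": 4, "common": 0}
    },
    "rice": {
      "genes": {"I": 10, "II": 13},
      "redundant": {"I": 137, "II": 106, "common": 24},
      "unique": {"I": 77, "II": 20, "common": 4}
    },
    "maize": {
      "genes": {"I": 10, "II": 9},
      "redundant": {"I": 265, "II": 130, "common": 107},
      "unique": {"I": 12, "II": 50, "common": 0}
    }
  },
  "PlantGDB": {
    "all": {
      "genes": {"I": 57, "II": 38},
      "redundant": {"I": 551, "II": 245, "common": 158},
      "unique": {"I": 106, "II": 148, "common": 3}
    },
    "arabidopsis": {
      "genes": {"I": 8, "II": 6},
      "redundant": {"I": 35, "II": 22, "common": 5},
      "unique": {"I": 23, "II": 2, "common": 0}
    },
    "rice": {
      "genes": {"I": 10, "II": 13},
      "redundant": {"I": 106, "II": 53, "common": 9},
      "unique": {"I": 41, "II": 8, "common": 0}
    },
    "maize": {
      "genes": {"I": 10, "II": 9},
      "redundant": {"I": 355, "II": 148, "common": 128},
      "unique": {"I": 22, "II": 124, "common": 2}
    }
  }
}
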