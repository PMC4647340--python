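<?xml version="1.0" encoding="UTF-8"?>
<xs:schema xmlns:xs="http://www.w3.org/2001/XMLSchema" elementFormDefault="unqualified">

  <xs:simpleType name="signedAxis">
    <xs:restriction base="xs:string">
      <xs:enumeration value="+x"/><xs:enumeration value="-x"/>
      <xs:enumeration value="+y"/><xs:enumeration value="-y"/>
      <xs:enumeration value="+z"/><xs:enumeration value="-z"/>
    </xs:restriction>
  </xs:simpleType>

  <xs:complexType name="axesType">
    <xs:sequence>
      <xs:element name="x" type="signedAxis"/>
      <xs:element name="y" type="signedAxis"/>
      <xs:element name="z" type="signedAxis"/>
    </xs:sequence>
  </xs:complexType>

  <xs:element name="acquisition">
    <xs:complexType>
      <xs:sequence>
        <xs:element name="lab">
          <xs:complexType>
            <xs:sequence>
              <xs:element name="units" type="xs:string" minOccurs="0"/>
              <xs:element name="axes" type="axesType"/>
              <xs:element name="forcePlatforms">
                <xs:complexType>
                  <xs:sequence>
                    <xs:element name="platform" maxOccurs="unbounded" minOccurs="0">
                      <xs:complexType>
                        <xs:sequence>
                          <xs:element name="channels" type="xs:string"/>
                          <xs:element name="sensorOffsets" minOccurs="0">
                            <xs:complexType>
                              <xs:attribute name="a" type="xs:double" use="required"/>
                              <xs:attribute name="b" type="xs:double" use="required"/>
                            </xs:complexType>
                          </xs:element>
                          <xs:element name="axes" type="axesType" minOccurs="0"/>
                        </xs:sequence>
                        <xs:attribute name="index" type="xs:positiveInteger" use="required"/>
                        <xs:attribute name="type" use="required">
                          <xs:simpleType>
                            <xs:restriction base="xs:integer">
                              <xs:minInclusive value="1"/>
                              <xs:maxInclusive value="4"/>
                            </xs:restriction>
                          </xs:simpleType>
                        </xs:attribute>
                      </xs:complexType>
                    </xs:element>
                  </xs:sequence>
                  <xs:attribute name="reaction" type="xs:boolean" default="true"/>
                </xs:complexType>
              </xs:element>
              <xs:element name="markerProtocol">
                <xs:complexType>
                  <xs:sequence>
                    <xs:element name="marker" type="xs:string" maxOccurs="unbounded" minOccurs="0"/>
                  </xs:sequence>
                </xs:complexType>
              </xs:element>
              <xs:element name="emgProtocol" minOccurs="0">
                <xs:complexType>
                  <xs:sequence>
                    <xs:element name="emg" maxOccurs="unbounded" minOccurs="0">
                      <xs:complexType>
                        <xs:attribute name="channel" type="xs:positiveInteger" use="required"/>
                        <xs:attribute name="muscle" type="xs:string" use="required"/>
                      </xs:complexType>
                    </xs:element>
                  </xs:sequence>
                </xs:complexType>
              </xs:element>
            </xs:sequence>
            <xs:attribute name="name" type="xs:string" use="required"/>
          </xs:complexType>
        </xs:element>
      </xs:sequence>
    </xs:complexType>
  </xs:element>
</xs:schema>
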